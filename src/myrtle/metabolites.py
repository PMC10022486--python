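"""Metabolite abundance clustering, accumulation rates and integration with
co-expression modules.

* Cluster number selection follows the cascade k-means approach: k-means is
  run for every k in a range and the Calinski–Harabasz criterion picks the
  best k (ties toward smaller k).  Metabolite profiles are z-scored across
  samples first, since raw abundances span orders of magnitude.
* The accumulation rate of metabolite n over consecutive fruit sampling
  times is the finite difference  V[t, n] = (M[t+1, n] - M[t, n]) / (T[t+1] - T[t]).
* Module–metabolite integration reports, for each (module, cluster) pair,
  the mean Pearson correlation of the module eigengene profile against each
  member metabolite (for rates, the eigengene is reduced to the same
  intervals by the same finite difference).
* Total anthocyanin content is quantified spectrophotometrically as
  (A530 - 0.25 · A657) / fresh weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score


@dataclass
class ClusterPartition:
    k: int
    labels: pd.Series              # metabolite -> cluster label in 1..k
    criterion: dict[int, float]    # k -> Calinski-Harabasz value


def _standardize_rows(df: pd.DataFrame) -> np.ndarray:
    x = df.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def kmeans_cascade(metab: pd.DataFrame, k_range: tuple[int, int] = (2, 12),
                   n_init: int = 10, seed: int = 1) -> ClusterPartition:
    """k-means over a range of k; Calinski–Harabasz picks the cluster number.

    Rows (metabolites) are z-scored across samples before clustering.
    k-means uses k-means++ initialisation with ``n_init`` restarts and a
    fixed seed, so the scan is reproducible.
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    n = metab.shape[0]
    if k_min < 2 or k_max >= n:
        raise ValueError(
            f"k range [{k_min}, {k_max}] must lie within [2, n_metabolites-1]"
            f" = [2, {n - 1}]"
        )
    if k_min > k_max:
        raise ValueError(f"empty k range [{k_min}, {k_max}]")
    x = _standardize_rows(metab)
    criterion: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(x)
        fits[k] = lab
        criterion[k] = (float(calinski_harabasz_score(x, lab))
                        if len(np.unique(lab)) > 1 else -np.inf)
    best_k = max(sorted(criterion), key=lambda k: (criterion[k], -k))
    labels = pd.Series(fits[best_k] + 1, index=metab.index, name="cluster")
    return ClusterPartition(k=best_k, labels=labels, criterion=criterion)


@dataclass
class AccumulationRate:
    rates: pd.DataFrame   # metabolites × intervals
    times: list[float]

    @property
    def intervals(self) -> list[str]:
        return list(self.rates.columns)


def accumulation_rate(metab: pd.DataFrame,
                      times: list[float]) -> AccumulationRate:
    """Per-interval accumulation rate V = ΔM / ΔT over consecutive stages.

    ``metab`` columns must be the stage samples in time order, one column per
    sampling time; ``times`` is the matching strictly increasing schedule
    (days after flowering).
    """
    times = [float(t) for t in times]
    if len(times) != metab.shape[1]:
        raise ValueError(
            f"{len(times)} times but {metab.shape[1]} stage columns"
        )
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError(f"times must be strictly increasing, got {times}")
    m = metab.to_numpy(dtype=float)
    dt = np.diff(times)
    v = np.diff(m, axis=1) / dt[None, :]
    cols = [f"{metab.columns[i]}_to_{metab.columns[i + 1]}"
            for i in range(len(times) - 1)]
    return AccumulationRate(
        rates=pd.DataFrame(v, index=metab.index, columns=cols), times=times)


def eigengene_rates(eigengenes: pd.DataFrame, stage_samples: list[str],
                    times: list[float]) -> pd.DataFrame:
    """Reduce eigengene sample profiles to stage intervals by the same finite
    difference used for metabolite accumulation rates.  Returns
    intervals × modules."""
    sub = eigengenes.loc[stage_samples]  # stages × modules
    rate = accumulation_rate(sub.T, times)
    return rate.rates.T


@dataclass
class IntegrationCorrelation:
    mean_r: pd.DataFrame       # modules × clusters, mean Pearson r
    per_metabolite: pd.DataFrame  # long table: module, cluster, metabolite, r

    def grid_argmax(self) -> tuple[str, object]:
        """(module, cluster) cell with the largest mean correlation."""
        stacked = self.mean_r.stack()
        module, cluster = stacked.idxmax()
        return module, cluster


def correlate_modules_metabolites(profiles: pd.DataFrame,
                                  metab: pd.DataFrame,
                                  partition: ClusterPartition
                                  ) -> IntegrationCorrelation:
    """Mean Pearson r between each module profile and each metabolite cluster.

    ``profiles`` is points × modules (eigengene values per sample, or per
    interval for accumulation rates); ``metab`` is metabolites × points on
    the same axis.  Cells with fewer than 3 shared points are NaN.
    """
    shared = [c for c in metab.columns if c in profiles.index]
    modules = list(profiles.columns)
    clusters = sorted(partition.labels.unique())
    rows = []
    for module in modules:
        x = profiles.loc[shared, module].to_numpy(dtype=float)
        for met in metab.index:
            y = metab.loc[met, shared].to_numpy(dtype=float)
            if len(shared) < 3 or np.std(x) == 0 or np.std(y) == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(x, y).statistic)
            rows.append({"module": module, "metabolite": met,
                         "cluster": partition.labels[met], "r": r})
    per_met = pd.DataFrame(rows)
    mean_r = (per_met.pivot_table(index="module", columns="cluster",
                                  values="r", aggfunc="mean")
              .reindex(index=modules, columns=clusters))
    return IntegrationCorrelation(mean_r=mean_r, per_metabolite=per_met)


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One spectrophotometric reading for anthocyanin quantification.

    A650/A666 (chlorophyll wavelengths) are stored when recorded but not used
    by the anthocyanin formula.
    """

    sample_id: str
    a530: float
    a657: float
    fresh_weight: float        # grams
    a650: float | None = None
    a666: float | None = None

    def __post_init__(self) -> None:
        if self.fresh_weight <= 0:
            raise ValueError(
                f"{self.sample_id}: fresh weight must be > 0, got "
                f"{self.fresh_weight}"
            )
        for name in ("a530", "a657"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.sample_id}: {name} must be >= 0")


def anthocyanin_value(rec: AbsorbanceRecord) -> float:
    """Total anthocyanin per gram fresh weight: (A530 - 0.25·A657) / FW."""
    return (rec.a530 - 0.25 * rec.a657) / rec.fresh_weight


def anthocyanin_table(records: list[AbsorbanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id,
        "a530": r.a530,
        "a657": r.a657,
        "fresh_weight_g": r.fresh_weight,
        "anthocyanin": anthocyanin_value(r),
    } for r in records])
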