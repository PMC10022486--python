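"""Weighted co-expression network analysis: soft threshold, topological
overlap, module detection, eigengenes and module–trait correlation.

The network is unsigned: adjacency a_ij = |cor(x_i, x_j)|^beta with the soft
threshold beta chosen as the lowest power whose degree distribution fits a
scale-free topology (R² of the log-log degree regression above a cut), the
standard WGCNA criterion.  Gene–gene similarity is the topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

modules come from average-linkage hierarchical clustering of 1 - TOM with a
static cut followed by eigengene-correlation merging, module eigengenes are
first principal-component sample profiles, and module–trait association is
Pearson correlation with the significance rule |r| > 0.8 and P < 0.001
(two-sided t test, n - 2 df, no multiple-testing correction).

The whole stage is deterministic: identical input and parameters give an
identical partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = "grey"


def _validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {expr.shape[1]}")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    variances = expr.var(axis=1, ddof=0)
    kept = expr.loc[variances > 0]
    dropped = expr.shape[0] - kept.shape[0]
    if dropped:
        import logging
        logging.getLogger("myrtle").info(
            "excluded %d zero-variance genes from network construction", dropped)
    if kept.shape[0] == 0:
        raise ValueError("all genes have zero variance")
    return kept


def adjacency(expr: pd.DataFrame, power: int) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |cor|^power, zero diagonal."""
    expr = _validate_expression(expr)
    corr = np.corrcoef(expr.to_numpy())
    a = np.abs(corr) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


@dataclass
class SoftThresholdScan:
    powers: list[int]
    r2: list[float]
    mean_connectivity: list[float]
    selected_power: int


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R² of log10(freq) on log10(mean k) over connectivity bins."""
    k = k[k > 0]
    if len(k) < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / len(k)))
    if len(xs) < 3:
        return 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue ** 2)


def pick_soft_threshold(expr: pd.DataFrame,
                        powers: list[int] | None = None,
                        r2_cut: float = 0.8) -> SoftThresholdScan:
    """Scan candidate powers; select the lowest with scale-free R² >= r2_cut,
    falling back to the power with maximal R² when none qualifies."""
    if powers is None:
        powers = list(range(1, 21))
    expr = _validate_expression(expr)
    if expr.shape[0] < 20:
        raise ValueError(f"need >= 20 genes for the scan, got {expr.shape[0]}")
    corr = np.abs(np.corrcoef(expr.to_numpy()))
    np.fill_diagonal(corr, 0.0)
    r2s, conn = [], []
    for beta in powers:
        a = corr ** beta
        k = a.sum(axis=0)
        r2s.append(_scale_free_fit(k))
        conn.append(float(k.mean()))
    qualifying = [p for p, r2 in zip(powers, r2s) if r2 >= r2_cut]
    selected = min(qualifying) if qualifying else powers[int(np.argmax(r2s))]
    return SoftThresholdScan(powers=list(powers), r2=r2s,
                             mean_connectivity=conn, selected_power=selected)


def tom_similarity(expr_or_adj: pd.DataFrame,
                   power: int | None = None) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned network.

    Pass an expression matrix together with ``power``, or a precomputed
    adjacency (zero diagonal) with ``power=None``.
    """
    if power is not None:
        if power < 1:
            raise ValueError(f"power must be >= 1, got {power}")
        adj = adjacency(expr_or_adj, power)
    else:
        adj = expr_or_adj
    a = adj.to_numpy(dtype=float)
    shared = a @ a
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.index)


@dataclass
class ModulePartition:
    labels: pd.Series                    # gene -> module label (or UNASSIGNED)
    sizes: dict = field(default_factory=dict)

    def module_genes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def modules(self) -> list[str]:
        return [m for m in self.sizes if m != UNASSIGNED]


def cut_modules(tom: pd.DataFrame, expr: pd.DataFrame,
                min_module_size: int = 30, cut_height: float = 0.25,
                merge_cut: float = 0.25) -> ModulePartition:
    """Modules from average-linkage clustering of the TOM dissimilarity.

    The dissimilarity 1 - TOM is rescaled to [0, 1], the dendrogram is cut
    statically at ``cut_height``, clusters below ``min_module_size`` become
    unassigned, and modules whose eigengenes correlate above ``1 - merge_cut``
    are merged iteratively until stable.
    """
    if min_module_size < 2:
        raise ValueError(f"min_module_size must be >= 2, got {min_module_size}")
    genes = list(tom.index)
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    off = d[np.triu_indices_from(d, k=1)]
    span = off.max() - off.min()
    if span > 0:
        d = (d - off.min()) / span
        np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    labels = pd.Series(index=genes, dtype=object)
    counts = pd.Series(raw).value_counts()
    keep = [c for c in counts.index if counts[c] >= min_module_size]
    # name modules M1, M2, ... in decreasing size order
    keep.sort(key=lambda c: (-counts[c], c))
    name_of = {c: f"M{i + 1}" for i, c in enumerate(keep)}
    for gene, c in zip(genes, raw):
        labels[gene] = name_of.get(c, UNASSIGNED)

    labels = _merge_close_modules(expr, labels, merge_cut)
    sizes = labels.value_counts().to_dict()
    return ModulePartition(labels=labels, sizes=sizes)


def _merge_close_modules(expr: pd.DataFrame, labels: pd.Series,
                         merge_cut: float) -> pd.Series:
    while True:
        modules = sorted(m for m in labels.unique() if m != UNASSIGNED)
        if len(modules) < 2:
            break
        eig = module_eigengenes(expr, ModulePartition(labels=labels))
        corr = eig.corr().to_numpy()
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= 1.0 - merge_cut:
            break
        a, b = eig.columns[i], eig.columns[j]
        labels = labels.replace(b, a)
    # re-normalise names to size order after merging
    counts = labels[labels != UNASSIGNED].value_counts()
    rename = {old: f"M{i + 1}"
              for i, old in enumerate(counts.sort_values(ascending=False).index)}
    return labels.map(lambda m: rename.get(m, UNASSIGNED))


def module_eigengenes(expr: pd.DataFrame,
                      partition: ModulePartition) -> pd.DataFrame:
    """First-principal-component sample profile of each module.

    Rows of the module submatrix are standardised before the SVD; each
    eigengene is scaled to unit sample variance and sign-aligned so it
    correlates positively with the module's mean expression profile.
    Returns samples × modules.
    """
    samples = expr.columns
    out = {}
    for module in sorted(m for m in partition.labels.unique() if m != UNASSIGNED):
        genes = partition.module_genes(module)
        if not genes:
            raise ValueError(f"module {module!r} is empty")
        sub = expr.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        sd_e = e.std(ddof=1)
        if sd_e > 0:
            e = (e - e.mean()) / sd_e
        out[module] = e
    return pd.DataFrame(out, index=samples)


@dataclass
class ModuleTraitCorrelation:
    r: pd.DataFrame            # modules × traits
    p: pd.DataFrame
    significant: pd.DataFrame  # boolean


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                             r_threshold: float = 0.8,
                             p_threshold: float = 0.001) -> ModuleTraitCorrelation:
    """Pearson r and two-sided p for each module × trait pair.

    ``traits`` is samples × traits (0/1 indicators or numeric covariates).
    A constant trait yields NaN r, flagged not significant.
    """
    if len(eigengenes) < 3:
        raise ValueError("need >= 3 samples for correlation")
    common = eigengenes.index.intersection(traits.index)
    if len(common) < 3:
        raise ValueError("eigengenes and traits share < 3 samples")
    eig = eigengenes.loc[common]
    tra = traits.loc[common]
    r = pd.DataFrame(index=eig.columns, columns=tra.columns, dtype=float)
    p = r.copy()
    for m in eig.columns:
        for t in tra.columns:
            x = eig[m].to_numpy(dtype=float)
            y = tra[t].to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(x) == 0:
                r.loc[m, t] = np.nan
                p.loc[m, t] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r.loc[m, t] = res.statistic
            p.loc[m, t] = res.pvalue
    significant = (r.abs() > r_threshold) & (p < p_threshold)
    significant = significant.fillna(False).astype(bool)
    return ModuleTraitCorrelation(r=r, p=p, significant=significant)
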