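"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and seed (same inputs →
byte-identical outputs) and returns machine-readable ground truth alongside
the data, so planted-structure recovery is directly testable.

Codon pairs
-----------
The codon-pair generator targets the NG86 site definition directly: an
ancestral stop-free sequence is drawn uniformly over sense codons, and each
codon position acquires a difference between the two descendant lineages with
probability p(d) · f, where f is the position's NG86 synonymous (or
nonsynonymous) site fraction and p(d) = (3/4)(1 - exp(-4d/3)) inverts the
Jukes–Cantor correction at the requested divergence d.  Synonymous
differences are drawn among the amino-acid-preserving single-nucleotide
changes, nonsynonymous ones among the non-stop amino-acid-changing changes;
substitutions that would create a stop codon are redrawn or dropped.  The
construction makes the *expected* NG86-counted divergence equal the requested
true_dS / true_dN; it is an estimator-consistency simulator, not a mechanistic
codon model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BedInterval, SequenceRecord
from .kaks import (CODON_TO_AA, SENSE_CODONS, STOP_CODONS, CodonPair)

_BASES = "ACGT"


def _jc_proportion(d: float) -> float:
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


# ---------------------------------------------------------------------------
# Codon pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonSimParams:
    n_codons: int = 300
    true_ds: float = 1.25
    true_dn: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_codons < 30:
            raise ValueError(f"n_codons must be >= 30, got {self.n_codons}")
        if self.true_ds < 0 or self.true_dn < 0:
            raise ValueError("divergences must be >= 0")
        for name, d in (("true_ds", self.true_ds), ("true_dn", self.true_dn)):
            if _jc_proportion(d) >= 0.7499:
                raise ValueError(
                    f"{name}={d} implies a difference proportion at the "
                    "Jukes-Cantor saturation bound (p >= 3/4): unreachable"
                )


def _position_alternatives(codon: str, pos: int) -> tuple[list[str], list[str]]:
    """(synonymous alts, nonsynonymous non-stop alts) at one codon position."""
    aa = CODON_TO_AA[codon]
    syn, non = [], []
    for base in _BASES:
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        (syn if CODON_TO_AA[alt] == aa else non).append(alt)
    return syn, non


def simulate_codon_pair(params: CodonSimParams,
                        rng: np.random.Generator | None = None) -> CodonPair:
    """One aligned descendant pair at the requested NG86 divergences.

    At most one planted difference per codon, selected with marginal
    probability p(d) · (site fraction) per position, so the expected NG86
    Sd (Nd) equals p(dS)·S (p(dN)·N) of the ancestral sequence exactly and
    every planted difference is classified unambiguously (no pathway
    averaging noise from intra-codon collisions).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p_s = _jc_proportion(params.true_ds)
    p_n = _jc_proportion(params.true_dn)
    anc = [SENSE_CODONS[i]
           for i in rng.integers(0, len(SENSE_CODONS), params.n_codons)]
    codons_a: list[str] = []
    codons_b: list[str] = []
    for codon in anc:
        ca = cb = codon
        events: list[tuple[float, int, list[str]]] = []
        total = 0.0
        for pos in range(3):
            syn_alts, non_alts = _position_alternatives(codon, pos)
            f_syn = len(syn_alts) / 3.0
            # nonsynonymous site fraction counts stop-creating changes too
            f_non = 1.0 - f_syn
            if syn_alts:
                events.append((p_s * f_syn, pos, syn_alts))
                total += p_s * f_syn
            if f_non > 0:
                # stop-creating substitutions are redrawn among the
                # amino-acid-changing sense alternatives
                events.append((p_n * f_non, pos, non_alts))
                total += p_n * f_non
        if total > 1.0:
            raise ValueError(
                f"divergences (dS={params.true_ds}, dN={params.true_dn}) "
                f"too large to plant one difference per codon ({codon}: "
                f"total probability {total:.3f} > 1)"
            )
        u = rng.random()
        acc = 0.0
        for prob, pos, alts in events:
            acc += prob
            if u < acc:
                if alts:
                    alt = alts[rng.integers(0, len(alts))]
                    if rng.integers(0, 2) == 0:
                        ca = alt
                    else:
                        cb = alt
                break
        codons_a.append(ca)
        codons_b.append(cb)
    return CodonPair(
        id_a=f"sim{params.seed}_a", id_b=f"sim{params.seed}_b",
        cds_a="".join(codons_a), cds_b="".join(codons_b))


def simulate_codon_pairs(params: CodonSimParams,
                         n_pairs: int) -> list[CodonPair]:
    """Independent replicate pairs from a single seeded stream."""
    rng = np.random.default_rng(params.seed)
    out = []
    for i in range(n_pairs):
        pair = simulate_codon_pair(params, rng=rng)
        out.append(CodonPair(f"pair{i}_a", f"pair{i}_b",
                             pair.cds_a, pair.cds_b))
    return out


# ---------------------------------------------------------------------------
# Genomes with planted telomeres and centromeric satellites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSimParams:
    n_chromosomes: int = 3
    chromosome_length: int = 2_000_000
    telomere_copies: int = 150
    monomer_length: int = 422
    centromere_monomer: str | None = None   # random of monomer_length if None
    centromere_copies: int = 500
    mutation_rate: float = 0.02             # per base, within the satellite
    gc_content: float = 0.40                # background composition
    seed: int = 1

    def __post_init__(self) -> None:
        telo = 7 * self.telomere_copies
        cen = self.monomer_len_effective * self.centromere_copies
        if 2 * telo + cen + 2 * 20_000 > self.chromosome_length:
            raise ValueError(
                "planted arrays do not fit inside the chromosome without overlap"
            )
        if not (0 <= self.gc_content <= 1):
            raise ValueError("gc_content must be in [0, 1]")

    @property
    def monomer_len_effective(self) -> int:
        return (len(self.centromere_monomer) if self.centromere_monomer
                else self.monomer_length)


@dataclass
class GenomeTruth:
    telomeres: list[BedInterval] = field(default_factory=list)
    centromeres: list[BedInterval] = field(default_factory=list)
    monomer: str = ""

    def to_dict(self) -> dict:
        as_d = lambda iv: {"chrom": iv.chrom, "start": iv.start,
                           "end": iv.end, "name": iv.name}
        return {"telomeres": [as_d(t) for t in self.telomeres],
                "centromeres": [as_d(c) for c in self.centromeres],
                "monomer": self.monomer}


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def simulate_genome(params: GenomeSimParams
                    ) -> tuple[list[SequenceRecord], GenomeTruth]:
    """Chromosomes with terminal telomere heptamer arrays and one mid-arm
    centromeric satellite array each; planted intervals returned as truth."""
    rng = np.random.default_rng(params.seed)
    monomer = params.centromere_monomer or _random_dna(
        rng, params.monomer_length, 0.5)
    truth = GenomeTruth(monomer=monomer)
    records: list[SequenceRecord] = []
    telo_len = 7 * params.telomere_copies
    for c in range(params.n_chromosomes):
        name = f"chr{c + 1}"
        L = params.chromosome_length
        background = _random_dna(rng, L, params.gc_content)
        seq = list(background)
        if telo_len:
            seq[0:telo_len] = "CCCTAAA" * params.telomere_copies
            seq[L - telo_len:L] = "TTTAGGG" * params.telomere_copies
            truth.telomeres.append(
                BedInterval(name, 0, telo_len, "telomere_5p"))
            truth.telomeres.append(
                BedInterval(name, L - telo_len, L, "telomere_3p"))
        array = _mutate(rng, monomer * params.centromere_copies,
                        params.mutation_rate)
        cen_start = L // 2 - len(array) // 2
        seq[cen_start:cen_start + len(array)] = array
        truth.centromeres.append(
            BedInterval(name, cen_start, cen_start + len(array),
                        f"centromere:{len(monomer)}"))
        records.append(SequenceRecord(id=name, sequence="".join(seq)))
    return records, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted co-expression modules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSimParams:
    n_modules: int = 4
    module_size: int = 50
    n_background: int = 50
    n_samples: int = 10
    noise_sd: float = 0.3
    trait_locked: bool = True     # latent profiles follow sample groups
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("need >= 4 samples")
        if self.n_modules > 0 and self.trait_locked \
                and self.n_samples < self.n_modules:
            raise ValueError("need at least one sample per trait group")


@dataclass
class ExpressionSim:
    expr: pd.DataFrame      # genes × samples
    labels: pd.Series       # gene -> planted module ("bg" for background)
    latents: pd.DataFrame   # samples × modules
    traits: pd.DataFrame    # samples × trait indicators (0/1)


def simulate_expression(params: ExpressionSimParams) -> ExpressionSim:
    """Planted-module expression data: gene = loading · latent + noise.

    With ``trait_locked`` the module latents are standardised indicators of
    disjoint sample groups, and the matching 0/1 trait design is returned."""
    rng = np.random.default_rng(params.seed)
    samples = [f"S{i + 1}" for i in range(params.n_samples)]
    module_names = [f"mod{i + 1}" for i in range(params.n_modules)]
    latents = {}
    traits = {}
    groups = np.array_split(np.arange(params.n_samples),
                            max(params.n_modules, 1))
    for m, mod in enumerate(module_names):
        if params.trait_locked:
            ind = np.zeros(params.n_samples)
            ind[groups[m]] = 1.0
            traits[mod] = ind.astype(int)
            latent = (ind - ind.mean()) / ind.std(ddof=0)
        else:
            latent = rng.normal(size=params.n_samples)
            latent = (latent - latent.mean()) / latent.std(ddof=0)
        latents[mod] = latent
    rows = {}
    labels = {}
    for mod in module_names:
        for g in range(params.module_size):
            gene = f"{mod}_g{g + 1}"
            load = rng.uniform(0.5, 1.0)
            rows[gene] = load * latents[mod] + \
                rng.normal(0.0, params.noise_sd, params.n_samples)
            labels[gene] = mod
    for g in range(params.n_background):
        gene = f"bg_g{g + 1}"
        rows[gene] = rng.normal(0.0, 1.0, params.n_samples)
        labels[gene] = "bg"
    expr = pd.DataFrame(rows, index=samples).T
    latents_df = pd.DataFrame(latents, index=samples)
    traits_df = (pd.DataFrame(traits, index=samples)
                 if traits else pd.DataFrame(index=samples))
    return ExpressionSim(expr=expr, labels=pd.Series(labels),
                         latents=latents_df, traits=traits_df)


# ---------------------------------------------------------------------------
# Metabolite time courses with planted clusters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaboliteSimParams:
    n_metabolites: int = 60
    n_clusters: int = 3
    n_samples: int = 6
    noise_sd: float = 0.1
    times: tuple = (45.0, 60.0, 75.0, 90.0)   # fruit-stage grid (days)
    seed: int = 1

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("time grid must be strictly increasing")
        if self.n_clusters < 1 or self.n_clusters >= self.n_metabolites:
            raise ValueError("need 1 <= n_clusters < n_metabolites")


@dataclass
class MetaboliteSim:
    matrix: pd.DataFrame    # metabolites × samples
    labels: pd.Series       # metabolite -> planted cluster (1..k)
    latents: pd.DataFrame   # samples × clusters


def simulate_metabolites(params: MetaboliteSimParams,
                         link: np.ndarray | pd.Series | None = None
                         ) -> MetaboliteSim:
    """Planted-cluster metabolite profiles (noisy copies of cluster latents).

    ``link``, if given, replaces cluster 1's latent with the supplied module
    profile (standardised), so module–metabolite integration has a known
    ground-truth maximum."""
    rng = np.random.default_rng(params.seed)
    samples = [f"T{i + 1}" for i in range(params.n_samples)]
    latents = rng.normal(size=(params.n_clusters, params.n_samples))
    latents = (latents - latents.mean(axis=1, keepdims=True)) / \
        latents.std(axis=1, ddof=0, keepdims=True)
    if link is not None:
        v = np.asarray(link, dtype=float)
        if len(v) != params.n_samples:
            raise ValueError("link profile length must equal n_samples")
        latents[0] = (v - v.mean()) / v.std(ddof=0)
    per = np.array_split(np.arange(params.n_metabolites), params.n_clusters)
    rows = {}
    labels = {}
    for c, members in enumerate(per):
        for i in members:
            met = f"met{i + 1}"
            rows[met] = latents[c] + rng.normal(0.0, params.noise_sd,
                                                params.n_samples)
            labels[met] = c + 1
    matrix = pd.DataFrame(rows, index=samples).T
    latents_df = pd.DataFrame(
        latents.T, index=samples,
        columns=[f"cluster{c + 1}" for c in range(params.n_clusters)])
    return MetaboliteSim(matrix=matrix, labels=pd.Series(labels),
                         latents=latents_df)
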