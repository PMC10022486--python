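"""Nei–Gojobori (1986) Ka/Ks estimation for pre-aligned coding sequence pairs.

The method counts, for each codon, the expected numbers of synonymous (S) and
nonsynonymous (N) *sites* — position by position, the fraction of the three
possible single-nucleotide changes that preserve the encoded amino acid — and
the numbers of synonymous (Sd) and nonsynonymous (Nd) *differences* between
the two sequences, averaging multi-hit codons over all mutational pathways.
The proportions pS = Sd/S and pN = Nd/N are then corrected for multiple hits
with the one-parameter Jukes–Cantor formula

    d = -(3/4) * ln(1 - (4/3) * p)

giving Ks (dS) and Ka (dN).  Conventions (the classic unweighted NG86):

* standard genetic code only;
* single-nucleotide changes that would create a stop codon count as
  nonsynonymous in site counting;
* mutational pathways passing through a stop codon are excluded from the
  pathway average (if every pathway is blocked, all pathways are used with
  stop-touching steps classed nonsynonymous);
* all pathways are weighted equally (no transition/transversion weighting).

Input pairs must already be aligned codon-to-codon; a strict validator
rejects length mismatches, gaps and stop codons.  Codons containing ``N`` in
either sequence are excluded pairwise from both site and difference counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
_BASES = "ACGT"

STATUS_OK = "ok"
STATUS_SATURATED = "saturated"
STATUS_UNDEFINED = "undefined"

# pS/pN at or beyond this bound make the Jukes-Cantor log undefined
_SATURATION = 0.75


@dataclass(frozen=True)
class CodonPair:
    """Two same-length, gap-free, codon-aligned CDS sequences."""

    id_a: str
    id_b: str
    cds_a: str
    cds_b: str

    def __post_init__(self) -> None:
        a, b = self.cds_a.upper(), self.cds_b.upper()
        object.__setattr__(self, "cds_a", a)
        object.__setattr__(self, "cds_b", b)
        if len(a) != len(b):
            raise ValueError(
                f"pair ({self.id_a},{self.id_b}): unequal lengths "
                f"{len(a)} vs {len(b)}"
            )
        if len(a) == 0 or len(a) % 3 != 0:
            raise ValueError(
                f"pair ({self.id_a},{self.id_b}): length {len(a)} not a "
                "positive multiple of 3"
            )
        for name, s in ((self.id_a, a), (self.id_b, b)):
            if "-" in s:
                raise ValueError(f"sequence {name!r}: gap characters not allowed")
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"sequence {name!r}: non-DNA characters {sorted(bad)}"
                )
            for i in range(0, len(s), 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"sequence {name!r}: stop codon {codon} at codon "
                        f"{i // 3} (trim terminal stops before analysis)"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.cds_a) // 3

    def codons(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.cds_a), 3):
            yield self.cds_a[i : i + 3], self.cds_b[i : i + 3]


@dataclass(frozen=True)
class SiteCounts:
    S: float
    N: float


@dataclass(frozen=True)
class DifferenceCounts:
    Sd: float
    Nd: float


@dataclass(frozen=True)
class KsEstimate:
    pair_id: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float
    ka: float
    omega: float
    status: str


@lru_cache(maxsize=None)
def codon_synonymous_fraction(codon: str) -> float:
    """Sum over the 3 positions of (synonymous single-nt changes)/3.

    Changes creating a stop codon are nonsynonymous by convention, so they do
    not contribute.
    """
    if codon in STOP_CODONS or codon not in CODON_TO_AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
    return syn / 3.0


def count_sites(cds: str) -> SiteCounts:
    """Expected synonymous/nonsynonymous site counts of one CDS.

    Codons containing ``N`` are skipped; S + N = 3 × (codons counted).
    """
    cds = cds.upper()
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a positive multiple of 3")
    S = 0.0
    counted = 0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            raise ValueError(f"stop codon {codon} at codon {i // 3}")
        S += codon_synonymous_fraction(codon)
        counted += 1
    return SiteCounts(S=S, N=3.0 * counted - S)


def _step_is_synonymous(c_from: str, c_to: str) -> bool:
    return CODON_TO_AA[c_from] == CODON_TO_AA[c_to]


@lru_cache(maxsize=None)
def _codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) contribution of one aligned codon pair."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    if len(diff_pos) == 1:
        if _step_is_synonymous(codon_a, codon_b):
            return (1.0, 0.0)
        return (0.0, 1.0)

    def walk(order: tuple[int, ...], count_stops_as_nonsyn: bool):
        """Follow one mutational ordering; None if it crosses a stop codon."""
        sd = nd = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                if not count_stops_as_nonsyn:
                    return None
                nd += 1.0
            elif _step_is_synonymous(cur, nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    orders = list(permutations(diff_pos))
    results = [r for o in orders if (r := walk(o, False)) is not None]
    if not results:  # every pathway blocked by a stop: fall back, stops → Nd
        results = [walk(o, True) for o in orders]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return (sd, nd)


def count_differences(pair: CodonPair) -> DifferenceCounts:
    """Pathway-averaged synonymous/nonsynonymous differences for a pair."""
    Sd = Nd = 0.0
    for ca, cb in pair.codons():
        if "N" in ca or "N" in cb:
            continue
        s, n = _codon_pair_differences(ca, cb)
        Sd += s
        Nd += n
    return DifferenceCounts(Sd=Sd, Nd=Nd)


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4)·ln(1 - (4/3)·p); NaN at saturation."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= _SATURATION:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(pair: CodonPair) -> KsEstimate:
    """Full NG86 estimate (sites, differences, JC-corrected Ks/Ka) for a pair.

    Saturation (pS or pN ≥ 3/4) is reported via ``status``, not raised.
    """
    S_vals = []
    N_vals = []
    Sd = Nd = 0.0
    for ca, cb in pair.codons():
        if "N" in ca or "N" in cb:
            continue
        fa = codon_synonymous_fraction(ca)
        fb = codon_synonymous_fraction(cb)
        S_vals.append((fa, fb))
        s, n = _codon_pair_differences(ca, cb)
        Sd += s
        Nd += n
    S = sum((fa + fb) / 2.0 for fa, fb in S_vals)
    N = 3.0 * len(S_vals) - S

    pair_id = f"{pair.id_a}|{pair.id_b}"
    if S <= 0 or N <= 0:
        return KsEstimate(pair_id, S, N, Sd, Nd, math.nan, math.nan,
                          math.nan, math.nan, math.nan, STATUS_UNDEFINED)
    pS = Sd / S
    pN = Nd / N
    ks = jukes_cantor(pS)
    ka = jukes_cantor(pN)
    if math.isnan(ks) or math.isnan(ka):
        status = STATUS_SATURATED
    else:
        status = STATUS_OK
    omega = ka / ks if (status == STATUS_OK and ks > 0) else math.nan
    return KsEstimate(pair_id, S, N, Sd, Nd, pS, pN, ks, ka, omega, status)


_TABLE_COLUMNS = ["pair_id", "S", "N", "Sd", "Nd", "pS", "pN", "ks", "ka",
                  "omega", "status"]


def ks_batch(pairs: Sequence[CodonPair]) -> pd.DataFrame:
    """NG86 estimates for many pairs, one row per pair in input order."""
    rows = []
    for idx, pair in enumerate(pairs):
        try:
            est = ng86(pair)
        except ValueError as exc:
            raise ValueError(
                f"invalid pair #{idx} ({pair.id_a},{pair.id_b}): {exc}"
            ) from exc
        rows.append({col: getattr(est, col if col != "pair_id" else "pair_id")
                     for col in _TABLE_COLUMNS})
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def pairs_from_records(records_a, records_b) -> list[CodonPair]:
    """Zip two equally long FASTA record lists into validated codon pairs."""
    if len(records_a) != len(records_b):
        raise ValueError(
            f"pair files differ in record count: {len(records_a)} vs "
            f"{len(records_b)}"
        )
    out = []
    for ra, rb in zip(records_a, records_b):
        try:
            out.append(CodonPair(ra.id, rb.id, ra.sequence, rb.sequence))
        except ValueError as exc:
            raise ValueError(f"pair ({ra.id},{rb.id}): {exc}") from exc
    return out
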