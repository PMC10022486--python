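"""Telomere and centromeric tandem-repeat annotation on assembled chromosomes.

Telomeres: plant chromosomes terminate in arrays of the heptamer CCCTAAA
(5' end, forward strand) / TTTAGGG (3' end, its reverse complement).  The
detector scans a terminal window at each chromosome end for maximal runs of
heptamer units, tolerating a configurable fraction of diverged units inside
a run.

Centromeres: centromeric satellites are high-copy tandem repeats with a
characteristic monomer (hundreds of bp).  The detector is a simplified
tandem-repeat finder: exact k-mer self-matches at a lag within the allowed
period range are chained into candidate arrays, a consensus monomer is
derived by column majority over the array cut into period-length frames, and
arrays are accepted on copy number and monomer identity.  Monomers are then
clustered into families by greedy centroid clustering under best-circular-
rotation ungapped identity (tandem monomer phase is arbitrary), and per
chromosome the strongest cluster of arrays from the genome-wide top families
is merged into at most one putative centromere span.

This is an approximation of the full alignment-scoring tandem-repeat
recursion, adequate for high-copy satellites; all coordinates are 0-based
half-open.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .io import SequenceRecord

logger = logging.getLogger("myrtle")

TELOMERE_FORWARD = "CCCTAAA"
TELOMERE_REVERSE = "TTTAGGG"  # reverse complement of the forward heptamer
_UNIT = 7

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class TelomereCall:
    chromosome: str
    end: str                 # five_prime / three_prime
    start: int
    stop: int
    copies: int              # matched heptamer units
    motif: str

    # BED adapter fields
    @property
    def chrom(self) -> str:
        return self.chromosome

    @property
    def name(self) -> str:
        return f"telomere_{'5p' if self.end == FIVE_PRIME else '3p'}:{self.motif}:{self.copies}"

    @property
    def score(self) -> float:
        return float(self.copies)


@dataclass
class TandemArray:
    chromosome: str
    start: int
    stop: int
    monomer: str
    period: int
    copies: float
    identity: float
    family: str | None = None

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class CentromereCall:
    chromosome: str
    start: int
    stop: int
    family_id: str
    monomer_length: int
    array_fraction: float

    @property
    def chrom(self) -> str:
        return self.chromosome

    @property
    def name(self) -> str:
        return f"{self.family_id}:{self.monomer_length}"

    @property
    def score(self) -> float:
        return round(self.array_fraction, 4)


# ---------------------------------------------------------------------------
# Telomeres
# ---------------------------------------------------------------------------

def _heptamer_runs(seq: str, motif: str, lo: int, hi: int, min_copies: int,
                   max_divergence: float) -> list[tuple[int, int, int]]:
    """Maximal chains of exact motif units in seq[lo:hi].

    Successive matched units may be separated by a small number of diverged
    units (spacing a multiple of the unit length); a run is kept when the
    overall diverged fraction is <= max_divergence and matched copies >=
    min_copies.  Returns (start, stop, matched_copies) in absolute coords.
    """
    hits = []
    pos = seq.find(motif, lo)
    while pos != -1 and pos + _UNIT <= hi:
        hits.append(pos)
        pos = seq.find(motif, pos + _UNIT)
    runs: list[tuple[int, int, int]] = []
    i = 0
    # at most this many consecutive diverged units may interrupt a run
    max_gap_units = 3
    while i < len(hits):
        start = hits[i]
        last = hits[i]
        matched = 1
        j = i + 1
        while j < len(hits):
            gap = hits[j] - last
            if gap % _UNIT == 0 and gap // _UNIT - 1 <= max_gap_units:
                last = hits[j]
                matched += 1
                j += 1
            else:
                break
        stop = last + _UNIT
        total_units = (stop - start) // _UNIT
        if matched >= min_copies and (1 - matched / total_units) <= max_divergence:
            runs.append((start, stop, matched))
        i = j
    return runs


def find_telomeres(chrom: SequenceRecord, window: int = 10_000,
                   min_copies: int = 10,
                   max_divergence: float = 0.1) -> list[TelomereCall]:
    """Scan the terminal windows of a chromosome for telomere heptamer arrays.

    Both motif orientations are searched in both windows and reported as
    found; chromosomes shorter than two windows are scanned whole (with a
    warning).
    """
    if window < _UNIT * min_copies:
        raise ValueError(
            f"window {window} too small for min_copies {min_copies}"
        )
    seq = chrom.sequence
    L = len(seq)
    if L < 2 * window:
        logger.warning(
            "%s: length %d < 2x window %d; scanning whole sequence",
            chrom.id, L, window)
        regions = [(FIVE_PRIME, 0, L)]
        if L > 0:
            regions.append((THREE_PRIME, 0, L))
    else:
        regions = [(FIVE_PRIME, 0, window), (THREE_PRIME, L - window, L)]

    calls: list[TelomereCall] = []
    seen: set[tuple[int, int, str]] = set()
    for end_label, lo, hi in regions:
        for motif in (TELOMERE_FORWARD, TELOMERE_REVERSE):
            for start, stop, copies in _heptamer_runs(
                    seq, motif, lo, hi, min_copies, max_divergence):
                key = (start, stop, motif)
                if key in seen:
                    continue
                seen.add(key)
                calls.append(TelomereCall(
                    chromosome=chrom.id, end=end_label, start=start,
                    stop=stop, copies=copies, motif=motif))
    calls.sort(key=lambda c: c.start)
    return calls


# ---------------------------------------------------------------------------
# Tandem arrays (simplified TRF)
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    valid = codes != 255
    return np.where(valid, codes, 0).astype(np.int64), valid


def _kmer_hashes(codes: np.ndarray, valid: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact integer hash of every k-mer (base-4 encoding; k <= 31)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    hashes = win @ powers
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return hashes, ok


def _self_match_seeds(hashes: np.ndarray, ok: np.ndarray, min_period: int,
                      max_period: int) -> tuple[np.ndarray, np.ndarray]:
    """(position, lag) pairs of identical k-mers with lag in the period range."""
    idx = np.nonzero(ok)[0]
    h = hashes[idx]
    order = np.argsort(h, kind="stable")
    h_sorted = h[order]
    pos_sorted = idx[order]
    bounds = np.nonzero(np.diff(h_sorted))[0] + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(h_sorted)]))
    seed_pos: list[np.ndarray] = []
    seed_lag: list[np.ndarray] = []
    for a, b in zip(starts, ends):
        if b - a < 2:
            continue
        group = np.sort(pos_sorted[a:b])
        j0 = 0
        for i in range(len(group)):
            # pairs (group[i], group[j]) with lag within [min_period, max_period]
            j = max(j0, i + 1)
            while j < len(group) and group[j] - group[i] < min_period:
                j += 1
            j0 = j
            jj = j
            while jj < len(group) and group[jj] - group[i] <= max_period:
                jj += 1
            if jj > j:
                lags = group[j:jj] - group[i]
                seed_pos.append(np.full(jj - j, group[i]))
                seed_lag.append(lags)
    if not seed_pos:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(seed_pos), np.concatenate(seed_lag)


def _consensus_and_identity(codes: np.ndarray, valid: np.ndarray, start: int,
                            stop: int, period: int) -> tuple[str, float, int, int]:
    """Column-majority consensus monomer and mean frame identity.

    Leading/trailing frames far below the array's core identity are trimmed so
    chained flanking noise does not dilute the call.
    """
    n_frames = (stop - start) // period
    if n_frames < 2:
        return "", 0.0, start, stop
    frames = codes[start : start + n_frames * period].reshape(n_frames, period)
    cons = np.empty(period, dtype=np.int64)
    for c in range(period):
        cons[c] = np.bincount(frames[:, c], minlength=4).argmax()
    ident = (frames == cons[None, :]).mean(axis=1)
    lo, hi = 0, n_frames
    while lo < hi and ident[lo] < 0.5:
        lo += 1
    while hi > lo and ident[hi - 1] < 0.5:
        hi -= 1
    if hi - lo < 2:
        return "", 0.0, start, stop
    mean_ident = float(ident[lo:hi].mean())
    monomer = "".join("ACGT"[b] for b in cons)
    return monomer, mean_ident, start + lo * period, start + hi * period


def find_tandem_arrays(chrom: SequenceRecord, min_period: int = 20,
                       max_period: int = 2000, min_copies: float = 5.0,
                       kmer: int = 13,
                       min_identity: float = 0.8) -> list[TandemArray]:
    """Detect tandem-repeat arrays with periods in [min_period, max_period].

    k-mer self-matches at a consistent lag are chained into candidate arrays;
    the lag estimates the period, a column-majority consensus defines the
    monomer, and candidates are accepted when mean monomer identity >=
    ``min_identity`` and copy number >= ``min_copies``.  Harmonic re-detections
    (the same array at a multiple of its period) are suppressed.
    """
    if min_period < 20:
        raise ValueError(f"min_period must be >= 20, got {min_period}")
    if max_period > 2000:
        raise ValueError(f"max_period must be <= 2000, got {max_period}")
    codes, valid = _encode(chrom.sequence)
    hashes, ok = _kmer_hashes(codes, valid, kmer)
    pos, lag = _self_match_seeds(hashes, ok, min_period, max_period)
    if len(pos) == 0:
        return []

    # cluster seed lags: adjacent lag values (within 3 bp) belong together
    uniq, counts = np.unique(lag, return_counts=True)
    min_seeds = max(5, int(min_copies))
    clusters: list[tuple[int, np.ndarray]] = []
    cur = [0]
    for i in range(1, len(uniq)):
        if uniq[i] - uniq[cur[-1]] <= 3:
            cur.append(i)
        else:
            clusters.append(_lag_cluster(uniq, counts, cur))
            cur = [i]
    clusters.append(_lag_cluster(uniq, counts, cur))

    arrays: list[TandemArray] = []
    for period, members in sorted(clusters, key=lambda c: c[0]):
        total = counts[np.isin(uniq, members)].sum()
        if total < min_seeds:
            continue
        sel = np.isin(lag, members)
        positions = np.sort(pos[sel])
        # chain positions: break when consecutive seeds are > one period apart
        breaks = np.nonzero(np.diff(positions) > period + 3)[0]
        seg_starts = np.concatenate(([0], breaks + 1))
        seg_ends = np.concatenate((breaks + 1, [len(positions)]))
        for a, b in zip(seg_starts, seg_ends):
            start = int(positions[a])
            stop = int(positions[b - 1]) + period + kmer
            stop = min(stop, len(chrom.sequence))
            if stop - start < 2 * period:
                continue
            if _is_harmonic(arrays, start, stop, period):
                continue
            monomer, ident, t_start, t_stop = _consensus_and_identity(
                codes, valid, start, stop, period)
            copies = (t_stop - t_start) / period
            if not monomer or ident < min_identity or copies < min_copies:
                continue
            arrays.append(TandemArray(
                chromosome=chrom.id, start=t_start, stop=t_stop,
                monomer=monomer, period=period, copies=round(copies, 2),
                identity=round(ident, 4)))
    arrays.sort(key=lambda arr: (arr.start, arr.period))
    return arrays


def _lag_cluster(uniq: np.ndarray, counts: np.ndarray,
                 idxs: list[int]) -> tuple[int, np.ndarray]:
    members = uniq[idxs]
    weights = counts[idxs]
    period = int(round(float(np.average(members, weights=weights))))
    return period, members


def _is_harmonic(accepted: list[TandemArray], start: int, stop: int,
                 period: int) -> bool:
    """True if a smaller-period accepted array already covers this candidate."""
    for arr in accepted:
        if arr.chromosome is None:
            continue
        overlap = min(stop, arr.stop) - max(start, arr.start)
        if overlap <= 0:
            continue
        if overlap / (stop - start) >= 0.5 and period >= arr.period:
            return True
    return False


# ---------------------------------------------------------------------------
# Monomer clustering (greedy centroid, circular-rotation identity)
# ---------------------------------------------------------------------------

def circular_identity(a: str, b: str) -> float:
    """Best ungapped identity of ``a`` vs any circular rotation of ``b``.

    Computed over the shorter length; 0 for wildly different lengths never
    reaches usual thresholds because the length mismatch itself caps identity.
    """
    if not a or not b:
        return 0.0
    m = min(len(a), len(b))
    length_penalty = m / max(len(a), len(b))
    ca = np.frombuffer(a.encode("ascii"), dtype=np.uint8)[:m]
    cb = np.frombuffer((b + b).encode("ascii"), dtype=np.uint8)
    best = 0
    for r in range(len(b)):
        matches = int((ca == cb[r : r + m]).sum())
        if matches > best:
            best = matches
            if best == m:
                break
    return best / m * length_penalty


def cluster_monomers(arrays: list[TandemArray],
                     identity_threshold: float = 0.8) -> dict[int, str]:
    """Assign each array to a monomer family by greedy centroid clustering.

    Arrays are visited in decreasing total length; an array joins the first
    family whose representative monomer matches at >= ``identity_threshold``
    under best circular rotation, else founds a new family.  Family labels
    are written onto the arrays and returned as {index in input: family}.
    """
    if not arrays:
        raise ValueError("no arrays to cluster")
    order = sorted(range(len(arrays)), key=lambda i: -arrays[i].length)
    reps: list[tuple[str, str]] = []  # (family_id, representative monomer)
    assignment: dict[int, str] = {}
    for i in order:
        arr = arrays[i]
        placed = None
        for fam_id, rep in reps:
            ratio = min(len(rep), len(arr.monomer)) / max(len(rep), len(arr.monomer))
            if ratio < identity_threshold:
                continue
            if circular_identity(arr.monomer, rep) >= identity_threshold:
                placed = fam_id
                break
        if placed is None:
            placed = f"fam{len(reps) + 1}"
            reps.append((placed, arr.monomer))
        assignment[i] = placed
        arr.family = placed
    return assignment


# ---------------------------------------------------------------------------
# Centromere calling
# ---------------------------------------------------------------------------

def call_centromeres(arrays: list[TandemArray], join_distance: int = 100_000,
                     top_families: int = 2,
                     min_span: int = 1000) -> list[CentromereCall]:
    """At most one putative centromere per chromosome.

    The genome-wide top satellite families (by summed array length) are the
    candidate centromeric repeats; per chromosome their arrays are merged
    within ``join_distance`` and the cluster with the largest total member
    length wins (ties: longer span, then leftmost).
    """
    if any(arr.family is None for arr in arrays):
        raise ValueError("run cluster_monomers before call_centromeres")
    fam_total: dict[str, int] = defaultdict(int)
    for arr in arrays:
        fam_total[arr.family] += arr.length
    top = {f for f, _ in sorted(fam_total.items(),
                                key=lambda kv: -kv[1])[:top_families]}

    by_chrom: dict[str, list[TandemArray]] = defaultdict(list)
    for arr in arrays:
        if arr.family in top:
            by_chrom[arr.chromosome].append(arr)

    calls: list[CentromereCall] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda a: a.start)
        clusters: list[list[TandemArray]] = [[members[0]]]
        for arr in members[1:]:
            if arr.start - clusters[-1][-1].stop <= join_distance:
                clusters[-1].append(arr)
            else:
                clusters.append([arr])
        scored = []
        for cl in clusters:
            total = sum(a.length for a in cl)
            span = cl[-1].stop - cl[0].start
            scored.append((total, span, -cl[0].start, cl))
        scored.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
        total, span, _, best = scored[0]
        start, stop = best[0].start, best[-1].stop
        if stop - start < min_span:
            logger.info("%s: no centromere call (best span %d < %d)",
                        chrom, stop - start, min_span)
            continue
        dom_fam: dict[str, int] = defaultdict(int)
        dom_period: dict[str, int] = {}
        for a in best:
            dom_fam[a.family] += a.length
            dom_period[a.family] = a.period
        family_id = max(dom_fam, key=dom_fam.get)
        calls.append(CentromereCall(
            chromosome=chrom, start=start, stop=stop, family_id=family_id,
            monomer_length=dom_period[family_id],
            array_fraction=total / (stop - start)))
    return calls


def arrays_table(arrays: list[TandemArray]):
    import pandas as pd

    return pd.DataFrame([{
        "chromosome": a.chromosome, "start": a.start, "stop": a.stop,
        "period": a.period, "copies": a.copies, "identity": a.identity,
        "family": a.family, "monomer": a.monomer,
    } for a in arrays])
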