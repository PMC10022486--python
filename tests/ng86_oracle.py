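"""Independent brute-force oracle for NG86 counting, used only by tests.

Deliberately shares no code with the implementation: translation goes
through Bio.Seq, difference counting enumerates every mutational ordering
recursively (no caching, no permutation shortcuts).
"""

from __future__ import annotations

from Bio.Seq import Seq

_BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_stop(codon: str) -> bool:
    return _aa(codon) == "*"


def oracle_site_counts(seq: str) -> tuple[float, float]:
    """(S, N) by direct enumeration of all 9 single-nucleotide changes."""
    S = 0.0
    n_codons = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        n_codons += 1
        for pos in range(3):
            syn = 0
            for base in _BASES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if not _is_stop(alt) and _aa(alt) == _aa(codon):
                    syn += 1
            S += syn / 3.0
    return S, 3.0 * n_codons - S


def _all_paths(cur: str, target: str):
    """Yield (sd, nd, crossed_stop) over every mutational ordering."""
    diffs = [i for i in range(3) if cur[i] != target[i]]
    if not diffs:
        yield (0.0, 0.0, False)
        return
    for i in diffs:
        nxt = cur[:i] + target[i] + cur[i + 1 :]
        stop = _is_stop(nxt)
        syn = (not stop) and _aa(cur) == _aa(nxt)
        for sd, nd, crossed in _all_paths(nxt, target):
            yield (sd + (1.0 if syn else 0.0),
                   nd + (0.0 if syn else 1.0),
                   crossed or stop)


def oracle_differences(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(Sd, Nd) by exhaustive pathway enumeration, stop paths excluded
    (falling back to all paths when every ordering crosses a stop)."""
    Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        paths = list(_all_paths(ca, cb))
        clean = [(sd, nd) for sd, nd, crossed in paths if not crossed]
        use = clean if clean else [(sd, nd) for sd, nd, _ in paths]
        Sd += sum(p[0] for p in use) / len(use)
        Nd += sum(p[1] for p in use) / len(use)
    return Sd, Nd
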