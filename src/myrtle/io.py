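"""Readers, writers, containers and run configuration shared by all pipeline stages.

Conventions
-----------
* All genomic coordinates are 0-based, half-open.  BED output follows the same
  convention; any 1-based display is formatting only.
* Stages never open files themselves: they consume :class:`SequenceRecord`
  objects and :class:`pandas.DataFrame` matrices produced by this module.
* Every stage logs its parameters at entry so a run can be re-created from its
  log alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("myrtle")

_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BedInterval:
    """A scored interval in 0-based half-open coordinates (BED6 line)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.chrom}:{self.start}-{self.end}: negative start")
        if self.start >= self.end:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: start must be < end"
            )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated :class:`SequenceRecord`.

    Records are returned in file order, sequences uppercased with line
    wrapping normalised away.  Duplicate ids, empty files and non-DNA
    characters (other than ``N``) are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature × sample TSV (header row of sample ids, first column of
    feature ids) into a numeric DataFrame.

    Ragged rows, duplicate ids and non-numeric cells are errors; the error
    for a bad cell names the offending row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty matrix file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: matrix has no data rows/columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column id {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(
            f"{path}: non-numeric or missing cell at row {r!r}, column {c!r} "
            f"(value {df.loc[r, c]!r})"
        )
    return numeric.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path,
                 index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_bed(calls: Sequence, path: str | Path) -> None:
    """Write calls as BED6, sorted by chromosome then start.

    Accepts :class:`BedInterval` or any object exposing
    ``chrom/start/end/name/score`` (``strand`` optional).  Call objects that
    use ``stop`` for the end coordinate (repeat calls) are handled too.
    """
    intervals = [
        BedInterval(
            chrom=c.chrom,
            start=int(c.start),
            end=int(c.stop if hasattr(c, "stop") else c.end),
            name=str(c.name),
            score=float(getattr(c, "score", 0.0)),
            strand=str(getattr(c, "strand", ".")),
        )
        for c in calls
    ]
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[BedInterval]:
    out: list[BedInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: expected ≥4 BED columns, got {line!r}")
            chrom, start, end, name = parts[:4]
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "."
            out.append(BedInterval(chrom, int(start), int(end), name, score, strand))
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULTS: dict = {
    "seed": 1,
    "wgd": {
        "filter_min": 0.01,
        "filter_max": 5.0,
        "grid_points": 512,
        "bandwidth": "silverman",
        "min_prominence_frac": 0.05,
    },
    "telomeres": {
        "window": 10_000,
        "min_copies": 10,
        "max_divergence": 0.1,
    },
    "centromeres": {
        "kmer": 13,
        "min_period": 20,
        "max_period": 2000,
        "min_copies": 5.0,
        "min_identity": 0.8,
        "identity_threshold": 0.8,
        "join_distance": 100_000,
        "top_families": 2,
        "min_span": 1000,
    },
    "coexpression": {
        "powers": list(range(1, 21)),
        "r2_cut": 0.8,
        "min_module_size": 30,
        "cut_height": 0.25,
        "merge_cut": 0.25,
        "r_threshold": 0.8,
        "p_threshold": 0.001,
    },
    "metabolites": {
        "k_min": 2,
        "k_max": 12,
        "n_init": 10,
        # post-flowering sampling schedule for the four fruit stages (days);
        # a configurable fixture, only the final 75 -> 90 interval is anchored
        "times": [45.0, 60.0, 75.0, 90.0],
    },
}


class PipelineConfig:
    """Stage-keyed parameter map with documented defaults.

    Unknown stages or parameter names are rejected so a typo in a config file
    cannot silently fall back to a default.
    """

    def __init__(self, overrides: Mapping | None = None) -> None:
        self._cfg = _deep_copy(DEFAULTS)
        if overrides:
            _deep_update(self._cfg, overrides, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls(data)

    @property
    def seed(self) -> int:
        return int(self._cfg["seed"])

    def stage(self, name: str) -> dict:
        if name not in self._cfg or not isinstance(self._cfg[name], dict):
            raise KeyError(f"unknown pipeline stage {name!r}")
        return dict(self._cfg[name])

    def get(self, stage: str, key: str):
        params = self.stage(stage)
        if key not in params:
            raise KeyError(f"unknown parameter {key!r} for stage {stage!r}")
        return params[key]

    def to_dict(self) -> dict:
        return _deep_copy(self._cfg)


def _deep_copy(d: dict) -> dict:
    return {k: _deep_copy(v) if isinstance(v, dict) else
            (list(v) if isinstance(v, list) else v) for k, v in d.items()}


def _deep_update(base: dict, overrides: Mapping, path: str) -> None:
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise KeyError(f"unknown configuration key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ValueError(f"configuration key {here!r} must be a mapping")
            _deep_update(base[key], value, here)
        else:
            base[key] = value


def log_stage(name: str, **params) -> None:
    """Echo a stage's parameters at INFO level (reproducibility aid)."""
    rendered = ", ".join(f"{k}={v!r}" for k, v in params.items())
    logger.info("stage %s: %s", name, rendered)
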