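"""Squiggle, ensemble and k-mer model containers plus their on-disk formats.

A *squiggle* is the step-current level series (picoamperes, one value per
segmented translocation event) produced by a nanopore device after event
segmentation.  The *gold standard model* is the expected squiggle for a known
reference: each k-mer window of the reference sequence mapped to its model
current level, so a perfect read has one event per k-mer.

Two plain-text squiggle dialects are supported:

``tsv_multi``
    one file, header ``read_id<TAB>levels``, levels comma-separated floats.
``per_file_text``
    one float per line, one file per read, ``read_id`` = file stem.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "Squiggle",
    "Ensemble",
    "KmerModel",
    "GoldModel",
    "SimTruth",
    "read_squiggles",
    "write_squiggles",
    "read_kmer_model",
    "read_reference",
    "gold_from_reference",
]


@dataclass
class SimTruth:
    """Ground-truth annotations attached by the simulator.

    ``source_positions[t]`` is the gold event index that emitted event ``t``
    of the read body (leader events excluded).
    """

    source_positions: np.ndarray | None = None
    leader_len: int = 0
    is_chimera: bool = False
    is_short: bool = False
    is_outlier: bool = False


@dataclass
class Squiggle:
    """One read's segmented step-current series.

    Parameters
    ----------
    read_id
        Unique identifier within an ensemble.
    levels
        Step-current values in pA, one per segmented event.
    leader_end
        Optional event index: events ``[0, leader_end)`` are leader.  Set by
        leader *detection*, never by the simulator (the simulated leader
        length lives in ``truth`` so detection can be scored against it).
    truth
        Optional simulation ground truth.
    """

    read_id: str
    levels: np.ndarray
    leader_end: int | None = None
    truth: SimTruth | None = None

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        if self.levels.ndim != 1 or self.levels.size == 0:
            raise ValueError(f"squiggle {self.read_id!r}: levels must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError(f"squiggle {self.read_id!r}: non-finite level")
        if self.leader_end is not None and not (0 <= self.leader_end <= len(self.levels)):
            raise ValueError(f"squiggle {self.read_id!r}: leader_end out of range")

    def __len__(self) -> int:
        return self.levels.size

    def body(self) -> np.ndarray:
        """Levels with any detected leader removed."""
        return self.levels if self.leader_end is None else self.levels[self.leader_end:]


@dataclass
class Ensemble:
    """An ordered collection of squiggles with unique read ids."""

    squiggles: list[Squiggle]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [s.read_id for s in self.squiggles]
        if len(set(ids)) != len(ids):
            raise ValueError(f"ensemble {self.label!r}: duplicate read_ids")

    def __len__(self) -> int:
        return len(self.squiggles)

    def __iter__(self) -> Iterator[Squiggle]:
        return iter(self.squiggles)

    def __getitem__(self, i: int) -> Squiggle:
        return self.squiggles[i]

    @property
    def read_ids(self) -> list[str]:
        return [s.read_id for s in self.squiggles]

    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.squiggles], dtype=np.int64)

    def level_arrays(self) -> list[np.ndarray]:
        return [s.levels for s in self.squiggles]

    def subset(self, keep_ids: set[str] | list[str], label: str | None = None) -> "Ensemble":
        keep = set(keep_ids)
        return Ensemble(
            [s for s in self.squiggles if s.read_id in keep],
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class KmerModel:
    """Map from k-mer (over A/C/G/T, U folded to T) to expected pA level."""

    k: int
    level_mean: Mapping[str, float]
    level_stdv: Mapping[str, float]

    def __post_init__(self) -> None:
        for kmer in self.level_mean:
            if len(kmer) != self.k:
                raise ValueError(f"k-mer {kmer!r} has length {len(kmer)}, expected k={self.k}")


@dataclass(frozen=True)
class GoldModel:
    """The gold-standard model squiggle for one reference sequence."""

    levels: np.ndarray
    source_sequence_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=np.float64))
        if self.levels.ndim != 1 or self.levels.size == 0:
            raise ValueError("gold model: levels must be a non-empty 1-D series")

    @property
    def gold_length(self) -> int:
        return self.levels.size


# ---------------------------------------------------------------------------
# squiggle files


def _format_levels(levels: np.ndarray) -> str:
    return ",".join(repr(float(x)) for x in levels)


def read_squiggles(path: str | Path, format: str = "tsv_multi") -> Ensemble:
    """Read an ensemble from disk.

    ``path`` is a file for ``tsv_multi``; for ``per_file_text`` it may be a
    single text file or a directory (all regular files, sorted by name).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "tsv_multi":
        return _read_tsv_multi(path)
    if format == "per_file_text":
        files = sorted(p for p in path.iterdir() if p.is_file()) if path.is_dir() else [path]
        return Ensemble([_read_per_file(p) for p in files], label=path.stem)
    raise ValueError(f"unknown squiggle format {format!r}")


def _read_tsv_multi(path: Path) -> Ensemble:
    squiggles = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t")[:2] != ["read_id", "levels"]:
            raise ValueError(f"{path}: line 1: expected header 'read_id\\tlevels'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1]:
                raise ValueError(f"{path}: line {lineno}: malformed record")
            try:
                levels = np.array([float(tok) for tok in parts[1].split(",")])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric level ({exc})") from None
            squiggles.append(Squiggle(parts[0], levels))
    if not squiggles:
        raise ValueError(f"{path}: no records")
    return Ensemble(squiggles, label=path.stem)


def _read_per_file(path: Path) -> Squiggle:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            try:
                values.append(float(tok))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric level {tok!r}") from None
    if not values:
        raise ValueError(f"{path}: empty record")
    return Squiggle(path.stem, np.array(values))


def write_squiggles(ensemble: Ensemble, path: str | Path, format: str = "tsv_multi") -> None:
    """Write an ensemble; round-trips bit-exactly through :func:`read_squiggles`."""
    if len(ensemble) == 0:
        raise ValueError("refusing to write an empty ensemble")
    path = Path(path)
    if format == "tsv_multi":
        with open(path, "w") as fh:
            fh.write("read_id\tlevels\n")
            for s in ensemble:
                fh.write(f"{s.read_id}\t{_format_levels(s.levels)}\n")
    elif format == "per_file_text":
        path.mkdir(parents=True, exist_ok=True)
        for s in ensemble:
            with open(path / f"{s.read_id}.txt", "w") as fh:
                fh.writelines(f"{float(x)!r}\n" for x in s.levels)
    else:
        raise ValueError(f"unknown squiggle format {format!r}")


# ---------------------------------------------------------------------------
# k-mer model and gold standard


def read_kmer_model(path: str | Path) -> KmerModel:
    """Read a pore model TSV with header ``kmer  level_mean  level_stdv``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("kmer", "level_mean"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    kmers = df["kmer"].astype(str).str.upper().str.replace("U", "T")
    if kmers.duplicated().any():
        dup = kmers[kmers.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate k-mer {dup!r}")
    lengths = kmers.str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"{path}: inconsistent k-mer lengths {sorted(lengths)}")
    means = dict(zip(kmers, df["level_mean"].astype(float)))
    if not all(np.isfinite(v) and v > 0 for v in means.values()):
        raise ValueError(f"{path}: level_mean values must be finite and positive")
    stdvs = (
        dict(zip(kmers, df["level_stdv"].astype(float)))
        if "level_stdv" in df.columns
        else {k: 0.0 for k in means}
    )
    return KmerModel(k=int(lengths[0]), level_mean=means, level_stdv=stdvs)


def read_reference(path: str | Path) -> tuple[str, str]:
    """Return ``(id, sequence)`` of the first FASTA record."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq)


def gold_from_reference(
    sequence: str,
    model: KmerModel,
    orientation: str = "three_prime",
    sequence_id: str = "",
) -> GoldModel:
    """Build the gold-standard model squiggle for a reference sequence.

    Each of the ``len(sequence) - k + 1`` k-mer windows maps to its model
    mean level.  ``three_prime`` enumerates windows starting from the 3' end
    (direct-RNA reads translocate 3'→5'); ``five_prime`` keeps natural order.
    """
    seq = sequence.upper().replace("U", "T")
    k = model.k
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} shorter than k={k}")
    n = len(seq) - k + 1
    levels = np.empty(n)
    for i in range(n):
        kmer = seq[i : i + k]
        try:
            levels[i] = model.level_mean[kmer]
        except KeyError:
            raise KeyError(f"k-mer {kmer!r} at position {i} not in model") from None
    if orientation == "three_prime":
        levels = levels[::-1].copy()
    elif orientation != "five_prime":
        raise ValueError(f"unknown orientation {orientation!r}")
    return GoldModel(levels=levels, source_sequence_id=sequence_id)
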