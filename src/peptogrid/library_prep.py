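"""Peptide-library curation.

Activity databases list peptides of mixed length with IC50 values of mixed
quality.  Screening a docking box sized for short peptides requires (i)
decomposing longer peptides into overlapping k-mers with a sliding window,
(ii) filtering activity entries to a trustworthy IC50 range, dropping
peptides with missing or mutually inconsistent measurements, and (iii)
merging libraries from several sources with deduplication.  Utilities here
also account for the combinatorial k-mer space (20^k for the standard
alphabet, e.g. 8000 tripeptides).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "PeptideEntry",
    "sliding_window",
    "filter_by_ic50",
    "combinatorial_space",
    "merge_dedup",
    "read_activity_table",
    "write_activity_table",
]

STANDARD_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PeptideEntry:
    """A peptide sequence with an optional IC50 activity (μM)."""

    sequence: str
    ic50: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence.upper()) - set(STANDARD_ALPHABET)
        if bad:
            raise ValueError(f"non-standard letters in {self.sequence!r}: {sorted(bad)}")
        if self.ic50 is not None and not self.ic50 > 0:
            raise ValueError(f"IC50 must be positive, got {self.ic50}")


def sliding_window(sequence: str, k: int) -> list[str]:
    """All length-k windows of *sequence* at step 1, in order, duplicates kept."""
    if k < 1:
        raise ValueError("window length must be >= 1")
    if k > len(sequence):
        raise ValueError(
            f"window length {k} exceeds sequence length {len(sequence)}"
        )
    return [sequence[i:i + k] for i in range(len(sequence) - k + 1)]


def filter_by_ic50(
    entries: Iterable[PeptideEntry],
    lower: float = 1.0,
    upper: float = 1000.0,
    diversity_tolerance: float = 2.0,
) -> tuple[list[PeptideEntry], list[tuple[str, str]]]:
    """Keep peptides with a single consistent IC50 inside [lower, upper] μM.

    Entries without a value are dropped ("missing").  A sequence listed with
    several IC50s is dropped as "multiple diverse values" when the ratio
    max/min exceeds *diversity_tolerance*; consistent repeats collapse to
    their median.  Bounds are inclusive.  Returns the surviving entries and
    a (sequence, reason) removal log.
    """
    groups: dict[str, list[Optional[float]]] = {}
    order: list[str] = []
    for e in entries:
        seq = e.sequence.upper()
        if seq not in groups:
            groups[seq] = []
            order.append(seq)
        groups[seq].append(e.ic50)
    kept: list[PeptideEntry] = []
    removed: list[tuple[str, str]] = []
    for seq in order:
        values = groups[seq]
        if any(v is None for v in values):
            removed.append((seq, "missing IC50"))
            continue
        vals = sorted(float(v) for v in values)
        if len(vals) > 1 and vals[-1] / vals[0] > diversity_tolerance:
            removed.append((seq, "multiple diverse values"))
            continue
        value = vals[len(vals) // 2] if len(vals) % 2 else (
            (vals[len(vals) // 2 - 1] + vals[len(vals) // 2]) / 2
        )
        if not (lower <= value <= upper):
            removed.append((seq, f"IC50 {value:g} outside [{lower:g}, {upper:g}]"))
            continue
        kept.append(PeptideEntry(sequence=seq, ic50=value))
    return kept, removed


def combinatorial_space(k: int, alphabet_size: int = 20) -> int:
    """Number of distinct k-mers over the alphabet: alphabet_size ** k."""
    if k < 1 or alphabet_size < 1:
        raise ValueError("k and alphabet_size must be >= 1")
    return alphabet_size ** k


@dataclass(frozen=True)
class MergeReport:
    union: tuple[str, ...]
    n_union: int
    n_intersection: int
    intersection: tuple[str, ...]


def merge_dedup(a: Iterable[str], b: Iterable[str]) -> MergeReport:
    """Case-normalized unique union of two sequence lists, with overlap counts."""
    set_a = {s.upper() for s in a}
    set_b = {s.upper() for s in b}
    inter = sorted(set_a & set_b)
    union = sorted(set_a | set_b)
    return MergeReport(
        union=tuple(union), n_union=len(union),
        n_intersection=len(inter), intersection=tuple(inter),
    )


def read_activity_table(path: str | Path, sep: str = "\t") -> list[PeptideEntry]:
    """Read a delimited table with columns ``sequence`` and ``ic50_um``."""
    df = pd.read_csv(path, sep=sep)
    if "sequence" not in df.columns:
        raise ValueError(f"{path}: missing 'sequence' column")
    entries = []
    for _, row in df.iterrows():
        ic50 = row.get("ic50_um")
        ic50 = None if ic50 is None or (isinstance(ic50, float) and math.isnan(ic50)) \
            else float(ic50)
        entries.append(PeptideEntry(sequence=str(row["sequence"]).strip(), ic50=ic50))
    return entries


def write_activity_table(entries: Iterable[PeptideEntry], path: str | Path,
                         sep: str = "\t") -> None:
    df = pd.DataFrame(
        [(e.sequence, e.ic50) for e in entries], columns=["sequence", "ic50_um"]
    )
    df.to_csv(path, sep=sep, index=False)
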