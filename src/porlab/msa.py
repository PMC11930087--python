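"""Per-position sequence variability from a protein multiple alignment.

Variability at a position is the percentage of sequences that do not carry
the most common residue there: v = 100 · (1 − n_mode / N).  Columns are
projected onto the numbering of a chosen reference sequence (columns where
the reference has a gap are unmapped), so the profile can be overlaid with
per-residue flexibility metrics on the same axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP_CHARS = frozenset("-.")


class AlignmentError(ValueError):
    """Raised for ragged alignments or a missing reference sequence."""


@dataclass(frozen=True)
class Alignment:
    """Equal-length aligned sequences with a designated reference row."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment is empty")
        length = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"ragged alignment: row {sid!r} has length {len(seq)}, expected {length}"
                )
        if self.reference_id not in self.ids:
            raise AlignmentError(f"reference id {self.reference_id!r} not in alignment")

    @property
    def reference_row(self) -> str:
        return self.sequences[self.ids.index(self.reference_id)]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])


def read_alignment(path, reference_id: str) -> Alignment:
    """Read an aligned FASTA file and validate it against a reference id."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no sequences found")
    return Alignment(
        ids=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
        reference_id=reference_id,
    )


def column_positions(alignment: Alignment, start: int = 1) -> dict[int, int]:
    """Map alignment column index -> reference residue number.

    Only columns where the reference carries a residue are mapped, numbered
    consecutively from ``start`` (configurable because reference numbering
    may begin past the transit peptide).
    """
    mapping = {}
    pos = start
    for col, ch in enumerate(alignment.reference_row):
        if ch not in GAP_CHARS:
            mapping[col] = pos
            pos += 1
    return mapping


def variability(
    alignment: Alignment, include_gaps: bool = False, start: int = 1
) -> pd.DataFrame:
    """Per-reference-position variability profile.

    For each mapped column, v = 100 · (1 − n_mode/N) where n_mode counts the
    most frequent residue symbol and N the sequences counted at that column.
    By default gaps are excluded from both counts (the metric measures
    disagreement among sequences that have a residue there);
    ``include_gaps=True`` counts the gap as an ordinary 21st symbol.
    Comparison is case-insensitive; ties on the modal residue leave v
    unchanged by construction.
    """
    if len(alignment.sequences) < 2:
        raise AlignmentError("variability requires at least 2 sequences")
    rows = []
    for col, pos in column_positions(alignment, start=start).items():
        symbols = [seq[col].upper() for seq in alignment.sequences]
        if not include_gaps:
            symbols = [s for s in symbols if s not in GAP_CHARS]
        else:
            symbols = ["-" if s in GAP_CHARS else s for s in symbols]
        if not symbols:
            v = 0.0
        else:
            _, counts = np.unique(symbols, return_counts=True)
            v = 100.0 * (1.0 - counts.max() / len(symbols))
        rows.append({"position": pos, "variability_percent": v})
    return pd.DataFrame(rows)


def overlay(rmsf_table: pd.DataFrame, variability_table: pd.DataFrame) -> pd.DataFrame:
    """Join a per-residue RMSF table and a variability profile on position,
    for the flexibility-vs-conservation overlay."""
    left = rmsf_table.rename(columns={"residue": "position"})
    return left.merge(variability_table, on="position", how="inner")
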