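"""Length-threshold partitioning and the statistics report.

The boundary rule is fixed: a record of length >= cutoff is "above", one of
length < cutoff is "below".  At the default nucleotide cutoff of 200 bp the
two sides are therefore labelled "above 199 bp" and "below 200 bp", the
convention used throughout file names, plot titles and the stats text.
200 bp is the minimum contig length accepted by the Transcriptome Shotgun
Assembly database, which is why it is the default; 100 aa is the common
open-reading-frame threshold used in protein mode.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

from .fasta_io import SequenceRecord

__all__ = [
    "UNITS",
    "RunConfig",
    "LengthPartition",
    "LengthStatsSummary",
    "partition_by_length",
    "compute_stats",
    "render_stats_text",
    "above_fasta_name",
    "below_fasta_name",
    "stats_file_name",
]

#: Length unit per sequence kind: base pairs / amino acids.
UNITS = {"nucleotide": "bp", "protein": "aa"}

DEFAULT_CUTOFF = 200
DEFAULT_BACKEND = "TkAgg"


@dataclass
class RunConfig:
    """All user-facing parameters of one run."""

    input_path: Union[str, os.PathLike]
    output_dir: Optional[Union[str, os.PathLike]] = None
    cutoff: int = DEFAULT_CUTOFF
    seq_kind: str = "nucleotide"
    show_plots: bool = False
    plot_backend: str = DEFAULT_BACKEND

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ValueError(f"cutoff must be >= 1, got {self.cutoff}")
        if self.seq_kind not in UNITS:
            raise ValueError(
                f"seq_kind must be one of {sorted(UNITS)}, got {self.seq_kind!r}"
            )

    @property
    def unit(self) -> str:
        """``"bp"`` for nucleotide input, ``"aa"`` for protein input."""
        return UNITS[self.seq_kind]


@dataclass
class LengthPartition:
    """Records split into the above/below sides of a cutoff.

    Every input record appears in exactly one side; input order is
    preserved within each side.
    """

    above: List[SequenceRecord] = field(default_factory=list)
    below: List[SequenceRecord] = field(default_factory=list)
    cutoff: int = DEFAULT_CUTOFF


@dataclass
class LengthStatsSummary:
    """Counts and length extremes for the input and both sides.

    Min/max of an empty side are ``None`` (rendered as ``N/A``), never 0:
    zero is a valid sequence length and would be misleading.
    """

    total_count: int
    above_count: int
    below_count: int
    above_min: Optional[int]
    above_max: Optional[int]
    below_min: Optional[int]
    below_max: Optional[int]
    input_min: Optional[int]
    input_max: Optional[int]
    cutoff: int
    unit: str


def partition_by_length(
    records: Sequence[SequenceRecord], cutoff: int
) -> LengthPartition:
    """Split *records* at *cutoff*: length >= cutoff goes above, else below."""
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    part = LengthPartition(cutoff=cutoff)
    for rec in records:
        (part.above if len(rec) >= cutoff else part.below).append(rec)
    return part


def _extremes(records: Sequence[SequenceRecord]) -> tuple[Optional[int], Optional[int]]:
    if not records:
        return None, None
    lengths = [len(r) for r in records]
    return min(lengths), max(lengths)


def compute_stats(partition: LengthPartition, unit: str) -> LengthStatsSummary:
    """Summarise a partition: counts plus min/max lengths of input and sides."""
    above_min, above_max = _extremes(partition.above)
    below_min, below_max = _extremes(partition.below)
    defined_mins = [v for v in (above_min, below_min) if v is not None]
    defined_maxs = [v for v in (above_max, below_max) if v is not None]
    return LengthStatsSummary(
        total_count=len(partition.above) + len(partition.below),
        above_count=len(partition.above),
        below_count=len(partition.below),
        above_min=above_min,
        above_max=above_max,
        below_min=below_min,
        below_max=below_max,
        input_min=min(defined_mins) if defined_mins else None,
        input_max=max(defined_maxs) if defined_maxs else None,
        cutoff=partition.cutoff,
        unit=unit,
    )


def _fmt(value: Optional[int]) -> str:
    return "N/A" if value is None else str(value)


def render_stats_text(summary: LengthStatsSummary) -> str:
    """Render the summary as labelled ``key: value`` lines.

    The layout is one number per line so that every figure can be read (or
    parsed) back unambiguously; the side labels embed the unit and the
    cutoff ("above {cutoff-1} {unit}" / "below {cutoff} {unit}").
    """
    c, u = summary.cutoff, summary.unit
    above = f"above {c - 1} {u}"
    below = f"below {c} {u}"
    lines = [
        f"Sequence length statistics (threshold {c} {u})",
        f"Total input sequences: {summary.total_count}",
        f"Input min length ({u}): {_fmt(summary.input_min)}",
        f"Input max length ({u}): {_fmt(summary.input_max)}",
        f"Sequences {above}: {summary.above_count}",
        f"Min length {above}: {_fmt(summary.above_min)}",
        f"Max length {above}: {_fmt(summary.above_max)}",
        f"Sequences {below}: {summary.below_count}",
        f"Min length {below}: {_fmt(summary.below_min)}",
        f"Max length {below}: {_fmt(summary.below_max)}",
    ]
    return "\n".join(lines) + "\n"


# Output-file naming.  The "seq_" / "seqs_" asymmetry between the two FASTA
# names is intentional: it reproduces the published file inventory verbatim.

def above_fasta_name(cutoff: int, unit: str) -> str:
    return f"seq_above{cutoff - 1}{unit}.fasta"


def below_fasta_name(cutoff: int, unit: str) -> str:
    return f"seqs_below{cutoff}{unit}.fasta"


def stats_file_name(cutoff: int) -> str:
    return f"seq_length_stats_by_threshold_{cutoff}.txt"
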