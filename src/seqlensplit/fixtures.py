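"""Seeded synthetic FASTA generation for tests and examples.

Real inputs for a length splitter are things like de novo transcriptome
assemblies (heavy-tailed contig lengths, hundreds of bp and up) and peptide
sets (tens of aa).  The generator emulates only what matters to this tool —
the length distribution, the alphabet and the FASTA layout — via three
samplers:

* ``LadderLengths``: deterministic consecutive lengths, for boundary tests;
* ``UniformLengths``: integers in [low, high];
* ``LogNormalLengths``: round(lognormal(mean_log, sigma_log)) truncated to
  >= 1 — the realistic default, matching the heavy right tail of assembled
  transcript lengths.

The same spec and seed always produce a byte-identical file.  Edge-case
flags inject an empty-sequence record, a duplicate identifier, or CRLF
line endings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import List, Union

import numpy as np

from .fasta_io import SequenceRecord, write_fasta

__all__ = [
    "FixtureConfigError",
    "LadderLengths",
    "UniformLengths",
    "LogNormalLengths",
    "FixtureSpec",
    "generate_fasta",
]

ALPHABETS = {
    "nucleotide": "ACGT",
    "protein": "ACDEFGHIKLMNPQRSTVWY",
}


class FixtureConfigError(ValueError):
    """Raised for invalid sampler or fixture parameters."""


@dataclass(frozen=True)
class LadderLengths:
    """Lengths start, start+1, ..., stop, cycling if more records are asked."""

    start: int = 1
    stop: int = 10

    def __post_init__(self) -> None:
        if self.start < 0 or self.stop < self.start:
            raise FixtureConfigError(
                f"ladder requires 0 <= start <= stop, got [{self.start}, {self.stop}]"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        span = self.stop - self.start + 1
        return self.start + (np.arange(n) % span)


@dataclass(frozen=True)
class UniformLengths:
    low: int = 1
    high: int = 500

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < self.low:
            raise FixtureConfigError(
                f"uniform requires 0 <= low <= high, got [{self.low}, {self.high}]"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.integers(self.low, self.high + 1, size=n)


@dataclass(frozen=True)
class LogNormalLengths:
    """Log-normal lengths; the median is exp(mean_log) (~403 at the default)."""

    mean_log: float = 6.0
    sigma_log: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise FixtureConfigError(
                f"log-normal sigma must be > 0, got {self.sigma_log}"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raw = rng.lognormal(self.mean_log, self.sigma_log, size=n)
        return np.maximum(1, np.rint(raw)).astype(np.int64)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic FASTA file."""

    n_records: int = 100
    lengths: Union[LadderLengths, UniformLengths, LogNormalLengths] = LogNormalLengths()
    alphabet: str = "nucleotide"
    wrap_width: int = 60
    seed: int = 0
    include_empty_record: bool = False
    include_duplicate_ids: bool = False
    crlf: bool = False

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise FixtureConfigError(f"n_records must be >= 1, got {self.n_records}")
        if self.alphabet not in ALPHABETS:
            raise FixtureConfigError(
                f"alphabet must be one of {sorted(ALPHABETS)}, got {self.alphabet!r}"
            )
        if self.wrap_width < 1:
            raise FixtureConfigError(f"wrap_width must be >= 1, got {self.wrap_width}")


def _random_residues(length: int, letters: str, rng: np.random.Generator) -> str:
    if length == 0:
        return ""
    codes = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)
    idx = rng.integers(0, len(codes), size=length)
    return codes[idx].tobytes().decode("ascii")


def generate_fasta(
    spec: FixtureSpec, path: Union[str, os.PathLike]
) -> List[SequenceRecord]:
    """Write a synthetic FASTA file at *path* and return its records.

    The returned records equal what :func:`~seqlensplit.fasta_io.read_fasta`
    recovers from the file; the same spec always yields identical bytes.
    """
    rng = np.random.default_rng(spec.seed)
    letters = ALPHABETS[spec.alphabet]
    lengths = spec.lengths.sample(spec.n_records, rng)
    records: List[SequenceRecord] = []
    for i, length in enumerate(lengths):
        records.append(
            SequenceRecord(
                identifier=f"seq{i + 1:05d}",
                description=f"synthetic length={int(length)}",
                residues=_random_residues(int(length), letters, rng),
            )
        )
    if spec.include_empty_record:
        records.append(SequenceRecord("seq_empty", "synthetic empty record", ""))
    if spec.include_duplicate_ids and records:
        first = records[0]
        records.append(
            SequenceRecord(first.identifier, "synthetic duplicate id", first.residues)
        )
    write_fasta(
        records,
        Path(path),
        wrap_width=spec.wrap_width,
        newline="\r\n" if spec.crlf else "\n",
    )
    return records
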