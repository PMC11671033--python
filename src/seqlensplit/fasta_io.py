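"""Reading and writing plain-text FASTA files.

The splitter must never drop, reorder or alter a record, so parsing is
deliberately permissive: multi-line (wrapped) sequences, CRLF or LF line
endings, blank lines inside and between records, empty sequence bodies and
duplicate identifiers are all accepted as-is.  Length is defined as the raw
character count of the residue string — gap (``-``) and stop (``*``)
symbols count, because silently excluding them would change which side of
the cutoff a record lands on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "SequenceRecord",
    "MalformedFastaError",
    "OutputWriteError",
    "read_fasta",
    "write_fasta",
]

PathLike = Union[str, os.PathLike]


class MalformedFastaError(ValueError):
    """Raised when a non-empty input file contains no ``>`` header line."""


class OutputWriteError(OSError):
    """Raised when an output file or directory cannot be written."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    Parameters
    ----------
    identifier
        First whitespace-delimited token after ``>`` on the header line.
    description
        Remainder of the header line; empty string when absent.
    residues
        The sequence itself with line breaks removed.  Case is preserved;
        ambiguity codes, gaps and stops are kept verbatim.
    """

    identifier: str
    description: str = ""
    residues: str = ""

    def __post_init__(self) -> None:
        if not self.identifier or any(c.isspace() for c in self.identifier):
            raise ValueError(
                f"identifier must be a non-empty whitespace-free token, "
                f"got {self.identifier!r}"
            )
        if any(c.isspace() or c == ">" for c in self.residues):
            raise ValueError("residues may not contain whitespace or '>'")

    def __len__(self) -> int:
        return len(self.residues)


def _split_header(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    if not parts:
        # ">" alone on a line: keep the record, give it a placeholder id
        return "_", ""
    return parts[0], parts[1].strip() if len(parts) > 1 else ""


def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Parse a FASTA file into an ordered list of :class:`SequenceRecord`.

    Records appear in file order.  Wrapped sequence lines are concatenated
    with surrounding whitespace removed; records with empty bodies are kept
    with length 0.  A zero-byte (or whitespace-only) file yields an empty
    list, but a file with content and no ``>`` header raises
    :class:`MalformedFastaError`.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist (message contains
        ``No such file or directory``).
    MalformedFastaError
        If the file is non-empty but contains no FASTA header.
    """
    path = Path(path)
    records: List[SequenceRecord] = []
    saw_content = False
    with open(path, "r", encoding="utf-8") as handle:
        # SimpleFastaParser silently skips text before the first header,
        # so headerless content must be detected separately.
        text = handle.read()
    saw_content = bool(text.strip())
    import io

    for title, seq in SimpleFastaParser(io.StringIO(text)):
        identifier, description = _split_header(title)
        records.append(SequenceRecord(identifier, description, seq))
    if saw_content and not records:
        raise MalformedFastaError(
            f"not a FASTA file (no '>' header found): {path}"
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: PathLike,
    wrap_width: int = 60,
    newline: str = "\n",
) -> int:
    """Write records to *path* in FASTA format; return the count written.

    Headers are ``>identifier description`` (single space, omitted when the
    description is empty); residues are wrapped at *wrap_width* characters.
    Re-reading the file with :func:`read_fasta` reproduces the input
    records exactly.
    """
    if wrap_width < 1:
        raise ValueError(f"wrap_width must be >= 1, got {wrap_width}")
    path = Path(path)
    count = 0
    try:
        with open(path, "w", encoding="utf-8", newline="") as handle:
            for rec in records:
                header = f">{rec.identifier}"
                if rec.description:
                    header += f" {rec.description}"
                handle.write(header + newline)
                for start in range(0, len(rec.residues), wrap_width):
                    handle.write(rec.residues[start : start + wrap_width] + newline)
                count += 1
    except OSError as exc:
        raise OutputWriteError(f"cannot write FASTA file {path}: {exc}") from exc
    return count
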