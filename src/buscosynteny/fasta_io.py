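"""Assembly FASTA input/output.

Scaffolds are exposed as :class:`SequenceRecord` objects — identifier, free-text
description, and the residue string with case preserved (soft-masked lowercase
is common in assemblies; all downstream counting is case-insensitive).
Plain and gzip-compressed FASTA are both accepted.
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import IntegrityError, ParseError

__all__ = ["SequenceRecord", "read_fasta", "write_fasta"]

_GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class SequenceRecord:
    """One FASTA scaffold: id (first header token), description, sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a nonempty token, got {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if any(c.isspace() for c in self.seq):
            raise ValueError(f"record {self.id!r} sequence contains whitespace")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: str | os.PathLike):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read all records of a FASTA file (plain or gzip), in file order.

    Raises :class:`ParseError` if the file does not begin with a header line,
    and :class:`IntegrityError` on duplicate record ids (downstream coordinate
    lookups require unique ids). An empty file yields an empty list with a
    warning.
    """
    with _open_text(path) as fh:
        # SeqIO silently discards text before the first '>', so validate the
        # head of the file ourselves to report the offending line.
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"expected FASTA header ('>'), got {line.strip()[:40]!r}",
                        path=path, line=lineno)
                break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise IntegrityError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].lstrip()
            if len(rec.seq) == 0:
                raise ParseError(f"record {rec.id!r} has an empty sequence",
                                 path=path)
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq),
                                          description=desc))
    return records


def write_fasta(records, path: str | os.PathLike, line_width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width``.

    ``read_fasta(write_fasta(x)) == x`` up to line wrapping. A ``.gz`` suffix
    selects gzip output.
    """
    if line_width < 1:
        raise ValueError(f"line_width must be positive, got {line_width}")
    seen: set[str] = set()
    bio_records = []
    for r in records:
        if r.id in seen:
            raise IntegrityError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
        bio_records.append(SeqRecord(Seq(r.seq), id=r.id, description=r.description))
    opener = gzip.open if os.fspath(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(bio_records)
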