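"""BUSCO full-table parsing, forward/reverse-complement merging, SCO extraction.

A BUSCO "full table" lists, for every ortholog in the lineage set, its status
(Complete, Duplicated, Fragmented, Missing) and — when found — its placement
in the assembly. Running BUSCO a second time on the reverse complement of the
assembly recovers orthologs the gene predictor misses on the forward strand;
:func:`merge_runs` combines the two runs, remapping reverse-complement
coordinates back onto forward-strand positions and keeping, per ortholog, the
record with the better status. The single-copy-ortholog (SCO) set — every
Complete ortholog with its unique placement — is the anchor set for synteny.

Two table dialects are autodetected: the v2/v3 column set
``id, Status, Contig, Start, End, Score, Length`` and the later v4/v5 layout
with a Strand column after End (plus optional trailing columns, ignored).
Coordinates are treated as 1-based inclusive; rows with Start > End (minus
strand in some builds) are normalized by swapping.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace

from ._util import CoordinateError, IntegrityError, ParseError, logger

__all__ = [
    "BuscoRecord", "OrthologPlacement", "BuscoSummary", "STATUSES",
    "parse_full_table", "summarize", "remap_revcomp", "merge_runs",
    "extract_sco_set", "read_scaffold_lengths",
]

STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")
_STATUS_RANK = {s: i for i, s in enumerate(STATUSES)}  # lower is better


@dataclass(frozen=True)
class BuscoRecord:
    """One full-table row. Placement fields are None iff status is Missing."""

    busco_id: str
    status: str
    scaffold_id: str | None = None
    start: int | None = None
    end: int | None = None
    score: float | None = None
    length: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown BUSCO status {self.status!r}")
        if self.status == "Missing":
            if self.scaffold_id is not None or self.start is not None:
                raise ValueError(f"{self.busco_id}: Missing row with placement")
        else:
            if self.scaffold_id is None or self.start is None or self.end is None:
                raise ValueError(f"{self.busco_id}: {self.status} row lacks placement")
            if self.start > self.end:
                raise ValueError(f"{self.busco_id}: start > end")


@dataclass(frozen=True)
class OrthologPlacement:
    """A single-copy ortholog's unique location in one genome."""

    busco_id: str
    chromosome_id: str
    start: int
    end: int
    source_direction: str = "forward"  # or "revcomp"


@dataclass(frozen=True)
class BuscoSummary:
    n_complete: int
    n_duplicated: int
    n_fragmented: int
    n_missing: int

    @property
    def n_total(self) -> int:
        return (self.n_complete + self.n_duplicated
                + self.n_fragmented + self.n_missing)


def _parse_row(fields: list[str], path, lineno: int) -> BuscoRecord:
    busco_id, status = fields[0], fields[1]
    if status not in STATUSES:
        raise ParseError(f"unknown BUSCO status {status!r}", path, lineno)
    if status == "Missing":
        return BuscoRecord(busco_id=busco_id, status=status)
    if len(fields) < 5:
        raise ParseError(f"{status} row has only {len(fields)} columns",
                         path, lineno)
    try:
        start, end = int(fields[3]), int(fields[4])
    except ValueError:
        raise ParseError(
            f"non-numeric coordinates {fields[3]!r}/{fields[4]!r}",
            path, lineno) from None
    strand = None
    rest = fields[5:]
    # v4/v5 dialect: a strand column sits between End and Score
    if rest and rest[0] in {"+", "-", "."}:
        strand = rest[0]
        rest = rest[1:]
    score = length = None
    try:
        if rest:
            score = float(rest[0])
        if len(rest) > 1:
            length = int(rest[1])
    except ValueError:
        raise ParseError(f"malformed score/length columns {rest!r}",
                         path, lineno) from None
    if start > end:
        logger.info("%s:%d: %s has start > end; swapping (minus strand)",
                    path, lineno, busco_id)
        start, end = end, start
    return BuscoRecord(busco_id=busco_id, status=status, scaffold_id=fields[2],
                       start=start, end=end, score=score, length=length,
                       strand=strand)


def parse_full_table(path: str | os.PathLike) -> list[BuscoRecord]:
    """Parse a BUSCO full_table TSV (v2–v5 dialects autodetected)."""
    records: list[BuscoRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("row has fewer than 2 tab-separated columns",
                                 path, lineno)
            records.append(_parse_row(fields, path, lineno))
    return records


def summarize(records) -> BuscoSummary:
    """Status counts. Duplicated orthologs are counted once, not per copy."""
    by_status: dict[str, set[str]] = {s: set() for s in STATUSES}
    for r in records:
        by_status[r.status].add(r.busco_id)
    return BuscoSummary(
        n_complete=len(by_status["Complete"]),
        n_duplicated=len(by_status["Duplicated"]),
        n_fragmented=len(by_status["Fragmented"]),
        n_missing=len(by_status["Missing"]),
    )


def remap_revcomp(record: BuscoRecord, scaffold_length: int) -> BuscoRecord:
    """Map a placement found on the reverse complement back to forward
    coordinates: [s, e] on a length-L scaffold becomes [L-e+1, L-s+1].

    The mapping is an involution and preserves interval length.
    """
    if record.status == "Missing":
        return record
    if record.end > scaffold_length:
        raise CoordinateError(
            f"{record.busco_id}: end {record.end} exceeds scaffold length "
            f"{scaffold_length}")
    return replace(record,
                   start=scaffold_length - record.end + 1,
                   end=scaffold_length - record.start + 1)


def _best_status(records) -> str:
    return min((r.status for r in records), key=_STATUS_RANK.__getitem__)


def merge_runs(forward, revcomp, scaffold_lengths: dict[str, int]):
    """Merge a forward and a reverse-complement BUSCO run.

    Per ortholog, the run with the better status wins under the precedence
    Complete > Duplicated > Fragmented > Missing; on a tie the forward run is
    kept. Reverse-complement placements are remapped to forward coordinates.
    An id present in only one run is treated as Missing in the other, with a
    warning. Returns the merged record list, ordered by busco_id.
    """
    fwd: dict[str, list[BuscoRecord]] = {}
    rev: dict[str, list[BuscoRecord]] = {}
    for r in forward:
        fwd.setdefault(r.busco_id, []).append(r)
    for r in revcomp:
        rev.setdefault(r.busco_id, []).append(r)
    only_f = fwd.keys() - rev.keys()
    only_r = rev.keys() - fwd.keys()
    if only_f or only_r:
        warnings.warn(
            f"busco_id universes differ between runs "
            f"({len(only_f)} forward-only, {len(only_r)} revcomp-only); "
            f"treating absent ids as Missing", stacklevel=2)

    merged: list[BuscoRecord] = []
    for bid in sorted(fwd.keys() | rev.keys()):
        f_recs = fwd.get(bid, [BuscoRecord(busco_id=bid, status="Missing")])
        r_recs = rev.get(bid, [BuscoRecord(busco_id=bid, status="Missing")])
        if _STATUS_RANK[_best_status(f_recs)] <= _STATUS_RANK[_best_status(r_recs)]:
            merged.extend(f_recs)
        else:
            for r in r_recs:
                if r.status == "Missing":
                    merged.append(r)
                    continue
                if r.scaffold_id not in scaffold_lengths:
                    raise CoordinateError(
                        f"{r.busco_id}: scaffold {r.scaffold_id!r} has no "
                        f"known length for revcomp remapping")
                merged.append(replace(
                    remap_revcomp(r, scaffold_lengths[r.scaffold_id]),
                    strand=None))
    return merged


def extract_sco_set(records) -> list[OrthologPlacement]:
    """The single-copy-ortholog placement set: Complete records only.

    Duplicated, Fragmented, and Missing orthologs are excluded — SCO synteny
    requires exactly one placement per ortholog. Two Complete records sharing
    a busco_id violate single-copy integrity and raise.
    """
    placements: dict[str, OrthologPlacement] = {}
    for r in records:
        if r.status != "Complete":
            continue
        if r.busco_id in placements:
            raise IntegrityError(
                f"busco_id {r.busco_id!r} has multiple Complete records; "
                f"not single-copy")
        placements[r.busco_id] = OrthologPlacement(
            busco_id=r.busco_id, chromosome_id=r.scaffold_id,
            start=r.start, end=r.end)
    return [placements[k] for k in sorted(placements)]


def read_scaffold_lengths(path: str | os.PathLike) -> dict[str, int]:
    """Scaffold lengths from a FASTA (plain/gzip) or a 2-column id<TAB>length TSV."""
    with open(path, "rb") as fh:
        head = fh.read(2)
    if head[:1] == b">" or head == b"\x1f\x8b":
        from .fasta_io import read_fasta
        return {r.id: len(r.seq) for r in read_fasta(path)}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError("expected 'id<TAB>length'", path, lineno)
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise ParseError(f"non-numeric length {parts[1]!r}",
                                 path, lineno) from None
    return lengths
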