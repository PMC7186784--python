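"""Circos karyotype and links file writers (and parsers for round-trips).

Karyotype lines use the standard dialect ``chr - ID LABEL START END COLOR``
with START fixed at 0 and END the chromosome length. Links use the modern
headerless two-segment-per-line dialect ``chrA startA endA chrB startB endB
[color=...]``. Output is byte-deterministic: links are ordered by
(chrom_a, start_a, busco_id). Link coordinates are written 1-based as parsed
(Circos tolerates this against 0-based karyotype ranges); a header comment in
each links file states the convention.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

from ._util import CoordinateError, IntegrityError, atomic_write

__all__ = [
    "KaryotypeEntry", "DEFAULT_PALETTE",
    "write_karyotype", "parse_karyotype", "write_links", "parse_links_file",
]

# one colour per genome-A chromosome, cycled; Circos named colours
DEFAULT_PALETTE = (
    "red", "orange", "yellow", "green", "blue", "purple", "vdred", "vdorange",
    "vdyellow", "vdgreen", "vdblue", "vdpurple", "lred", "lorange", "lyellow",
    "lgreen", "lblue", "lpurple", "dred", "dorange", "dyellow", "dgreen",
    "dblue", "dpurple", "grey",
)
FALLBACK_COLOR = "black"  # chromosomes outside the focal set


@dataclass(frozen=True)
class KaryotypeEntry:
    chrom_id: str
    label: str
    end: int
    color: str
    start: int = 0

    def __post_init__(self) -> None:
        if self.end <= 0:
            raise ValueError(f"{self.chrom_id}: length must be positive")


def write_karyotype(chromosomes, path: str | os.PathLike) -> None:
    """Write (id, length, label, color) tuples or KaryotypeEntry objects."""
    entries = [c if isinstance(c, KaryotypeEntry)
               else KaryotypeEntry(chrom_id=c[0], end=c[1], label=c[2],
                                   color=c[3])
               for c in chromosomes]
    seen: set[str] = set()
    for e in entries:
        if e.chrom_id in seen:
            raise IntegrityError(f"duplicate karyotype id {e.chrom_id!r}")
        seen.add(e.chrom_id)
    with atomic_write(path) as fh:
        for e in entries:
            fh.write(f"chr - {e.chrom_id} {e.label} {e.start} {e.end} "
                     f"{e.color}\n")


def parse_karyotype(path: str | os.PathLike) -> list[KaryotypeEntry]:
    entries: list[KaryotypeEntry] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7 or parts[0] != "chr" or parts[1] != "-":
                raise IntegrityError(f"{path}: malformed karyotype line "
                                     f"{line.strip()!r}")
            entries.append(KaryotypeEntry(
                chrom_id=parts[2], label=parts[3], start=int(parts[4]),
                end=int(parts[5]), color=parts[6]))
    return entries


def _assign_colors(chrom_ids) -> dict[str, str]:
    ordered = sorted(set(chrom_ids))
    return {c: DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
            for i, c in enumerate(ordered)}


def write_links(links, path: str | os.PathLike, color_by: str = "none",
                karyotype=None, strict: bool = False) -> None:
    """Write synteny links in Circos two-segment format.

    ``color_by`` is "chrom_a", "chrom_b", or "none"; colouring cycles the
    default 25-colour palette over the chosen genome's chromosomes. With a
    ``karyotype`` (KaryotypeEntry list covering both genomes), links that
    reference an absent chromosome or exceed its length warn, or raise when
    ``strict``.
    """
    if color_by not in {"chrom_a", "chrom_b", "none"}:
        raise ValueError(f"color_by must be chrom_a/chrom_b/none, got {color_by!r}")
    ordered = sorted(links, key=lambda l: (l.chrom_a, l.start_a, l.busco_id))
    colors: dict[str, str] = {}
    if color_by == "chrom_a":
        colors = _assign_colors(l.chrom_a for l in ordered)
    elif color_by == "chrom_b":
        colors = _assign_colors(l.chrom_b for l in ordered)

    bounds = {k.chrom_id: k.end for k in karyotype} if karyotype else None
    with atomic_write(path) as fh:
        fh.write("# circos links; coordinates 1-based inclusive as parsed "
                 "from BUSCO tables\n")
        for l in ordered:
            if bounds is not None:
                for chrom, end in ((l.chrom_a, l.end_a), (l.chrom_b, l.end_b)):
                    if chrom not in bounds:
                        msg = (f"link {l.busco_id}: chromosome {chrom!r} "
                               f"absent from karyotype")
                        if strict:
                            raise CoordinateError(msg)
                        warnings.warn(msg, stacklevel=2)
                    elif end > bounds[chrom]:
                        msg = (f"link {l.busco_id}: end {end} exceeds "
                               f"{chrom} length {bounds[chrom]}")
                        if strict:
                            raise CoordinateError(msg)
                        warnings.warn(msg, stacklevel=2)
            line = (f"{l.chrom_a} {l.start_a} {l.end_a} "
                    f"{l.chrom_b} {l.start_b} {l.end_b}")
            if color_by == "chrom_a":
                line += f" color={colors[l.chrom_a]}"
            elif color_by == "chrom_b":
                line += f" color={colors[l.chrom_b]}"
            fh.write(line + "\n")


def parse_links_file(path: str | os.PathLike):
    """Parse a two-segment Circos links file back to coordinate tuples.

    Returns (chrom_a, start_a, end_a, chrom_b, start_b, end_b, color-or-None)
    tuples; busco ids are not stored in Circos links and cannot be recovered.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            color = None
            if len(parts) == 7 and parts[6].startswith("color="):
                color = parts[6][len("color="):]
                parts = parts[:6]
            if len(parts) != 6:
                raise IntegrityError(f"{path}: malformed links line "
                                     f"{line.strip()!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2]),
                         parts[3], int(parts[4]), int(parts[5]), color))
    return rows
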