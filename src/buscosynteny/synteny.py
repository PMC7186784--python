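"""Synteny link construction, single-relocation filtering, block chaining.

A synteny link is one single-copy ortholog shared by two genomes, carrying its
coordinates in both. Links whose chromosome pair is supported by fewer than
``min_links`` shared orthologs are "single relocations" (at the default
min_links=2): one ortholog cannot evidence a rearrangement, so such links are
removed before events are interpreted. Links can optionally be chained into
positional blocks along genome A; the event logic itself operates at
whole-chromosome resolution, so chaining is off (unlimited gap) by default.
"""

from __future__ import annotations

import csv
import os
from collections import Counter
from dataclasses import dataclass

from ._util import IntegrityError, ParameterError, atomic_write, logger

__all__ = [
    "SyntenyLink", "SyntenyBlock",
    "build_links", "filter_single_relocations", "chain_blocks",
    "write_links_tsv", "read_links_tsv",
]

_LINK_COLUMNS = ("busco_id", "chrom_a", "start_a", "end_a",
                 "chrom_b", "start_b", "end_b")


@dataclass(frozen=True)
class SyntenyLink:
    """One shared SCO with 1-based inclusive coordinates in both genomes."""

    busco_id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int

    def __post_init__(self) -> None:
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise ValueError(f"{self.busco_id}: start > end")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.chrom_a, self.chrom_b)

    def swapped(self) -> "SyntenyLink":
        """The same link viewed from genome B's side."""
        return SyntenyLink(self.busco_id, self.chrom_b, self.start_b,
                           self.end_b, self.chrom_a, self.start_a, self.end_a)


@dataclass
class SyntenyBlock:
    """A run of links sharing one chromosome pair, ordered along genome A."""

    chrom_a: str
    chrom_b: str
    links: list[SyntenyLink]

    @property
    def n_links(self) -> int:
        return len(self.links)

    @property
    def span_a(self) -> tuple[int, int]:
        return (min(l.start_a for l in self.links),
                max(l.end_a for l in self.links))

    @property
    def span_b(self) -> tuple[int, int]:
        return (min(l.start_b for l in self.links),
                max(l.end_b for l in self.links))


def _check_unique(placements, label: str) -> dict:
    by_id = {}
    for p in placements:
        if p.busco_id in by_id:
            raise IntegrityError(
                f"duplicate busco_id {p.busco_id!r} in SCO set {label}")
        by_id[p.busco_id] = p
    return by_id


def build_links(sco_a, sco_b) -> list[SyntenyLink]:
    """One link per ortholog Complete (single-copy) in both genomes.

    Orthologs present in only one SCO set are dropped; the drop counts are
    logged. Output is sorted by (chrom_a, start_a, busco_id).
    """
    a = _check_unique(sco_a, "A")
    b = _check_unique(sco_b, "B")
    shared = a.keys() & b.keys()
    logger.info("build_links: %d shared SCOs (%d only in A, %d only in B)",
                len(shared), len(a) - len(shared), len(b) - len(shared))
    links = [
        SyntenyLink(busco_id=bid,
                    chrom_a=a[bid].chromosome_id, start_a=a[bid].start,
                    end_a=a[bid].end,
                    chrom_b=b[bid].chromosome_id, start_b=b[bid].start,
                    end_b=b[bid].end)
        for bid in shared
    ]
    links.sort(key=lambda l: (l.chrom_a, l.start_a, l.busco_id))
    return links


def filter_single_relocations(links, min_links: int = 2) -> list[SyntenyLink]:
    """Remove links whose (chrom_a, chrom_b) pair has < ``min_links`` support.

    With the default of 2 this removes exactly the singleton chromosome-pair
    links — the "single relocations" dropped before interpreting synteny.
    """
    if min_links < 1:
        raise ParameterError(f"min_links must be >= 1, got {min_links}")
    support = Counter(l.pair for l in links)
    kept = [l for l in links if support[l.pair] >= min_links]
    logger.info("filter_single_relocations: removed %d of %d links "
                "(min_links=%d)", len(links) - len(kept), len(links), min_links)
    return kept


def chain_blocks(links, max_gap_a: int | None = None) -> list[SyntenyBlock]:
    """Partition links into blocks of consecutive same-pair links on A.

    Links are ordered by (chrom_a, start_a); consecutive links with the same
    chromosome pair whose distance on A is <= ``max_gap_a`` join one block
    (``None`` = unlimited, so a block is all same-pair links on a chromosome).
    Every link lands in exactly one block.
    """
    ordered = sorted(links, key=lambda l: (l.chrom_a, l.start_a, l.busco_id))
    blocks: list[SyntenyBlock] = []
    for link in ordered:
        prev = blocks[-1] if blocks else None
        if (prev is not None and prev.chrom_a == link.chrom_a
                and prev.chrom_b == link.chrom_b
                and (max_gap_a is None
                     or link.start_a - prev.links[-1].end_a <= max_gap_a)):
            prev.links.append(link)
        else:
            blocks.append(SyntenyBlock(link.chrom_a, link.chrom_b, [link]))
    return blocks


def write_links_tsv(links, path: str | os.PathLike) -> None:
    """Write links as a 7-column TSV with a header row."""
    with atomic_write(path) as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_LINK_COLUMNS)
        for l in links:
            w.writerow([l.busco_id, l.chrom_a, l.start_a, l.end_a,
                        l.chrom_b, l.start_b, l.end_b])


def read_links_tsv(path: str | os.PathLike) -> list[SyntenyLink]:
    with open(path) as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header is None or tuple(header) != _LINK_COLUMNS:
            raise IntegrityError(f"{path}: not a links TSV (bad header)")
        return [SyntenyLink(row[0], row[1], int(row[2]), int(row[3]),
                            row[4], int(row[5]), int(row[6])) for row in r]
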