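"""Chromosome fusion/fission event detection from synteny links.

Filtered links induce a bipartite graph: one node per chromosome of each
genome, one edge per chromosome pair that shares single-copy orthologs,
weighted by the number of shared orthologs. Each connected component of this
graph is a cluster of homologous chromosomes and is classified by its shape:

* 1 chromosome of A vs 1 of B — one-to-one, no event;
* 1 of A vs b > 1 of B — the A chromosome corresponds to b separate B
  chromosomes: a fusion in the A lineage or equivalently a fission in B's
  (b - 1 events);
* a > 1 of A vs 1 of B — the mirror case (a - 1 events);
* a > 1 vs b > 1 — complex; a + b - 2 is the minimum number of fusions plus
  fissions that can connect the component, reported as a lower bound.

Two genomes alone cannot polarize an event (which lineage fused vs which
fissioned); the report labels counts as relative. With a third genome as an
outgroup, :func:`polarize` assigns each event by parsimony: the state shared
by two of the three genomes is ancestral, so the event belongs to the third's
lineage.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import networkx as nx

from ._util import ParameterError, atomic_write
from .synteny import filter_single_relocations

__all__ = [
    "HomologyEdge", "HomologyComponent", "EventReport",
    "build_graph", "classify_component", "event_report", "polarize",
    "write_event_tsv", "format_event_summary",
]

ORIENTATION_NOTE = ("event counts are relative between the two genomes; "
                    "lineage polarity requires an outgroup")


@dataclass(frozen=True)
class HomologyEdge:
    chrom_a: str
    chrom_b: str
    n_links: int


@dataclass
class HomologyComponent:
    """One connected component of the chromosome-pair bipartite graph."""

    chroms_a: frozenset[str]
    chroms_b: frozenset[str]
    edges: frozenset[HomologyEdge]
    classification: str = field(init=False)
    n_events: int = field(init=False)

    def __post_init__(self) -> None:
        self.classification, self.n_events = classify_component(
            len(self.chroms_a), len(self.chroms_b))

    @property
    def n_links(self) -> int:
        return sum(e.n_links for e in self.edges)


@dataclass
class EventReport:
    components: list[HomologyComponent]
    unlinked_a: list[str]
    unlinked_b: list[str]
    orientation_note: str = ORIENTATION_NOTE

    @property
    def n_one_to_one(self) -> int:
        return sum(c.classification == "one_to_one" for c in self.components)

    @property
    def n_fusions_in_a(self) -> int:
        return sum(c.n_events for c in self.components
                   if c.classification == "fusion_in_a")

    @property
    def n_fissions_in_a(self) -> int:
        return sum(c.n_events for c in self.components
                   if c.classification == "fission_in_a")

    @property
    def n_complex(self) -> int:
        return sum(c.classification == "complex" for c in self.components)


def build_graph(links) -> nx.Graph:
    """Bipartite graph over chromosomes; edge weight = supporting link count.

    Nodes are tagged ("A", chrom) / ("B", chrom) so identically named
    chromosomes of the two genomes stay distinct.
    """
    g = nx.Graph()
    for link in links:
        u, v = ("A", link.chrom_a), ("B", link.chrom_b)
        if g.has_edge(u, v):
            g[u][v]["weight"] += 1
        else:
            g.add_edge(u, v, weight=1)
    return g


def classify_component(a: int, b: int) -> tuple[str, int]:
    """Classification and event count for a component with ``a`` chromosomes
    of genome A and ``b`` of genome B.

    For complex components (a > 1 and b > 1) the count a + b - 2 is the
    minimum number of fusion+fission operations that can explain a connected
    component; the true history may be longer.
    """
    if a < 1 or b < 1:
        raise ParameterError("component must touch both genomes")
    if a == 1 and b == 1:
        return "one_to_one", 0
    if a == 1:
        return "fusion_in_a", b - 1
    if b == 1:
        return "fission_in_a", a - 1
    return "complex", a + b - 2


def event_report(links, min_links: int = 2,
                 chroms_a=None, chroms_b=None) -> EventReport:
    """Full pipeline: filter -> graph -> components -> classify -> aggregate.

    ``chroms_a``/``chroms_b`` optionally give the complete chromosome sets so
    chromosomes with no surviving link can be listed as unlinked (they are
    never counted as events).
    """
    filtered = filter_single_relocations(links, min_links=min_links)
    g = build_graph(filtered)
    components: list[HomologyComponent] = []
    for nodes in nx.connected_components(g):
        ca = frozenset(c for side, c in nodes if side == "A")
        cb = frozenset(c for side, c in nodes if side == "B")
        edges = frozenset(
            HomologyEdge(chrom_a=u[1], chrom_b=v[1], n_links=d["weight"])
            if u[0] == "A" else
            HomologyEdge(chrom_a=v[1], chrom_b=u[1], n_links=d["weight"])
            for u, v, d in g.subgraph(nodes).edges(data=True))
        components.append(HomologyComponent(ca, cb, edges))
    components.sort(key=lambda c: (sorted(c.chroms_a), sorted(c.chroms_b)))

    linked_a = {c for comp in components for c in comp.chroms_a}
    linked_b = {c for comp in components for c in comp.chroms_b}
    unlinked_a = sorted(set(chroms_a) - linked_a) if chroms_a else []
    unlinked_b = sorted(set(chroms_b) - linked_b) if chroms_b else []
    return EventReport(components=components, unlinked_a=unlinked_a,
                       unlinked_b=unlinked_b)


def polarize(report: EventReport, links_a_out, links_out_b,
             min_links: int = 2) -> dict[int, str]:
    """Assign each non-one-to-one component to a lineage using an outgroup.

    ``links_a_out`` are A-vs-outgroup links and ``links_out_b`` are
    outgroup-vs-B links (outgroup on the A side). For a component where one A
    chromosome matches several B chromosomes, the outgroup breaks the tie: if
    the outgroup also holds the region on a single chromosome, the split state
    of B is derived (fission in B's lineage); if the outgroup is split like B,
    the joined state of A is derived (fusion in A's lineage). Mirror logic for
    the opposite shape. Returns {component index: "fusion_in_a" |
    "fission_in_b" | "fission_in_a" | "fusion_in_b" | "unresolved"}.
    """
    out_of_a = _partner_map(
        filter_single_relocations(links_a_out, min_links=min_links),
        side="a")
    out_of_b = _partner_map(
        [l.swapped() for l in
         filter_single_relocations(links_out_b, min_links=min_links)],
        side="a")

    calls: dict[int, str] = {}
    for i, comp in enumerate(report.components):
        if comp.classification == "fusion_in_a":
            (chrom_a,) = comp.chroms_a
            n_out = len(out_of_a.get(chrom_a, set()))
            if n_out <= 1:
                # outgroup joined like A -> joined is ancestral -> B fissioned
                calls[i] = "fission_in_b"
            elif n_out >= len(comp.chroms_b):
                calls[i] = "fusion_in_a"
            else:
                calls[i] = "unresolved"
        elif comp.classification == "fission_in_a":
            (chrom_b,) = comp.chroms_b
            n_out = len(out_of_b.get(chrom_b, set()))
            if n_out <= 1:
                calls[i] = "fission_in_a"
            elif n_out >= len(comp.chroms_a):
                calls[i] = "fusion_in_b"
            else:
                calls[i] = "unresolved"
        elif comp.classification == "complex":
            calls[i] = "unresolved"
    return calls


def _partner_map(links, side: str) -> dict[str, set[str]]:
    partners: dict[str, set[str]] = {}
    for l in links:
        if side == "a":
            partners.setdefault(l.chrom_a, set()).add(l.chrom_b)
        else:
            partners.setdefault(l.chrom_b, set()).add(l.chrom_a)
    return partners


def write_event_tsv(report: EventReport, path: str | os.PathLike) -> None:
    with atomic_write(path) as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["component", "chroms_a", "chroms_b", "classification",
                    "n_links", "n_events"])
        for i, c in enumerate(report.components, start=1):
            w.writerow([i, ",".join(sorted(c.chroms_a)),
                        ",".join(sorted(c.chroms_b)),
                        c.classification, c.n_links, c.n_events])


def format_event_summary(report: EventReport) -> str:
    lines = [
        f"components: {len(report.components)}",
        f"  one-to-one: {report.n_one_to_one}",
        f"  fusion-in-A events (= fission-in-B): {report.n_fusions_in_a}",
        f"  fission-in-A events (= fusion-in-B): {report.n_fissions_in_a}",
        f"  complex components (event counts are minima): {report.n_complex}",
    ]
    if report.unlinked_a or report.unlinked_b:
        lines.append(f"  unlinked chromosomes: A={report.unlinked_a} "
                     f"B={report.unlinked_b}")
    lines.append(f"note: {report.orientation_note}")
    return "\n".join(lines) + "\n"
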