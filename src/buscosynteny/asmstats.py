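"""Assemblathon-style assembly statistics.

Computes the full contiguity/composition metric set for an assembly at both
scaffold and contig level. Contigs are the maximal spans of each scaffold that
contain no run of >= ``min_gap`` consecutive N (default 10); the separating
N-runs are gaps. A scaffold with at least one qualifying gap is "scaffolded"
and its contigs count as "in scaffolds"; a gap-free scaffold is itself one
"unscaffolded" contig.

Conventions (isolated here so they can be audited in one place):

* Nx is the length of the sequence at which the descending cumulative length
  first reaches ceil(x% of total); Lx is its 1-based rank. Totals include N.
* Means are reported rounded to the nearest integer (mean contigs per scaffold
  to one decimal); the median of an even count is the lower central value.
* Size-class percentages ("scaffolds >1K nt") are percentages of *count*.
* Composition is case-insensitive and percentages are over all residues
  including N; non-ACGTN collects the remaining IUPAC ambiguity codes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass

from ._util import ParameterError
from .fasta_io import SequenceRecord

__all__ = [
    "ContigSpan", "NxEntry", "LevelStats", "AssemblyReport",
    "split_into_contigs", "nx_series", "composition", "assembly_report",
    "format_report",
]

NX_PERCENTAGES = (50, 60, 70, 80, 90)
SIZE_THRESHOLDS = (1_000, 10_000, 100_000, 1_000_000, 10_000_000)
_THRESHOLD_LABELS = {1_000: "1K", 10_000: "10K", 100_000: "100K",
                     1_000_000: "1M", 10_000_000: "10M"}


@dataclass(frozen=True)
class ContigSpan:
    """A maximal gap-free span of a scaffold, 1-based inclusive coordinates."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span [{self.start},{self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class NxEntry:
    x: int
    n_length: int
    l_count: int


@dataclass
class LevelStats:
    """Count/size/Nx/composition block for one level (scaffold or contig)."""

    count: int
    total_size: int
    longest: int
    shortest: int
    thresholds: dict[int, tuple[int, float]]   # size -> (count, % of count)
    mean: int
    median: int
    nx: list[NxEntry]
    composition: dict[str, tuple[int, float]]  # A/C/G/T/N/other -> (count, %)


@dataclass
class AssemblyReport:
    scaffold: LevelStats
    contig: LevelStats
    n_contigs_in_scaffolds: int
    n_contigs_not_in_scaffolds: int
    pct_in_scaffolded_contigs: float
    pct_in_unscaffolded_contigs: float
    mean_contigs_per_scaffold: float
    mean_gap_length: int
    n_gaps: int
    total_gap_length: int

    def to_dict(self) -> dict:
        def level(s: LevelStats) -> dict:
            return {
                "count": s.count,
                "total_size": s.total_size,
                "longest": s.longest,
                "shortest": s.shortest,
                "thresholds": {_THRESHOLD_LABELS[t]: {"count": c, "pct": p}
                               for t, (c, p) in s.thresholds.items()},
                "mean": s.mean,
                "median": s.median,
                "nx": {str(e.x): {"n": e.n_length, "l": e.l_count} for e in s.nx},
                "composition": {b: {"count": c, "pct": p}
                                for b, (c, p) in s.composition.items()},
            }
        return {
            "scaffold": level(self.scaffold),
            "contig": level(self.contig),
            "n_contigs_in_scaffolds": self.n_contigs_in_scaffolds,
            "n_contigs_not_in_scaffolds": self.n_contigs_not_in_scaffolds,
            "pct_in_scaffolded_contigs": self.pct_in_scaffolded_contigs,
            "pct_in_unscaffolded_contigs": self.pct_in_unscaffolded_contigs,
            "mean_contigs_per_scaffold": self.mean_contigs_per_scaffold,
            "mean_gap_length": self.mean_gap_length,
            "n_gaps": self.n_gaps,
            "total_gap_length": self.total_gap_length,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def split_into_contigs(record: SequenceRecord, min_gap: int = 10,
                       ) -> tuple[list[ContigSpan], list[int]]:
    """Decompose one scaffold into contig spans and gap lengths.

    Gaps are N-runs (case-insensitive) of length >= ``min_gap``; shorter runs
    stay inside contigs. Leading/trailing qualifying runs produce no empty
    contig but still count as gaps.
    """
    if min_gap < 1:
        raise ParameterError(f"min_gap must be >= 1, got {min_gap}")
    contigs: list[ContigSpan] = []
    gaps: list[int] = []
    pos = 1  # 1-based start of the next potential contig
    for m in re.finditer("[Nn]{%d,}" % min_gap, record.seq):
        gap_start, gap_end = m.start() + 1, m.end()
        if gap_start > pos:
            contigs.append(ContigSpan(record.id, pos, gap_start - 1))
        gaps.append(gap_end - gap_start + 1)
        pos = gap_end + 1
    if pos <= len(record.seq):
        contigs.append(ContigSpan(record.id, pos, len(record.seq)))
    return contigs, gaps


def nx_series(lengths, x_values=NX_PERCENTAGES) -> list[NxEntry]:
    """Nx/Lx over descending-sorted lengths, for each x in ``x_values``.

    Nx = length of the sequence at which the cumulative total first reaches
    ceil(x% of total); Lx = its 1-based rank.
    """
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ParameterError("nx_series requires at least one length")
    total = sum(lengths)
    out: list[NxEntry] = []
    for x in x_values:
        target = -(-total * x // 100)  # ceil
        cum = 0
        for rank, length in enumerate(lengths, start=1):
            cum += length
            if cum >= target:
                out.append(NxEntry(x=x, n_length=length, l_count=rank))
                break
    return out


def composition(records) -> dict[str, tuple[int, float]]:
    """Case-insensitive residue counts and percentages for A/C/G/T/N/other.

    ``records`` may be SequenceRecords or plain sequence strings. Percentages
    are over the full residue count (N included); "other" is every residue
    outside {A,C,G,T,N}, i.e. the IUPAC ambiguity codes.
    """
    counts = {b: 0 for b in "ACGTN"}
    total = 0
    for rec in records:
        seq = rec.seq if hasattr(rec, "seq") else rec
        up = seq.upper()
        total += len(up)
        for b in "ACGTN":
            counts[b] += up.count(b)
    counts["other"] = total - sum(counts[b] for b in "ACGTN")
    if total == 0:
        raise ParameterError("composition requires at least one residue")
    return {b: (c, 100.0 * c / total) for b, c in counts.items()}


def _median_lower(sorted_desc: list[int]) -> int:
    # lower central value for even counts; integer output as in the report
    n = len(sorted_desc)
    asc = sorted_desc[::-1]
    if n % 2 == 1:
        return asc[n // 2]
    return min(asc[n // 2 - 1], asc[n // 2])


def _level_stats(lengths: list[int], comp: dict[str, tuple[int, float]],
                 ) -> LevelStats:
    lengths = sorted(lengths, reverse=True)
    n = len(lengths)
    total = sum(lengths)
    thresholds = {}
    for t in SIZE_THRESHOLDS:
        c = sum(1 for length in lengths if length > t)
        thresholds[t] = (c, 100.0 * c / n)
    return LevelStats(
        count=n,
        total_size=total,
        longest=lengths[0],
        shortest=lengths[-1],
        thresholds=thresholds,
        mean=round(total / n),
        median=_median_lower(lengths),
        nx=nx_series(lengths),
        composition=comp,
    )


def assembly_report(records, min_gap: int = 10) -> AssemblyReport:
    """Compute the full scaffold- and contig-level report for an assembly."""
    records = list(records)
    if not records:
        raise ParameterError("assembly_report requires at least one record")

    scaffold_lengths: list[int] = []
    contig_lengths: list[int] = []
    contig_seqs: list[str] = []
    gap_lengths: list[int] = []
    n_in_scaffolds = 0
    n_not_in_scaffolds = 0
    bases_in_scaffolded = 0
    bases_in_unscaffolded = 0

    for rec in records:
        scaffold_lengths.append(len(rec.seq))
        contigs, gaps = split_into_contigs(rec, min_gap=min_gap)
        gap_lengths.extend(gaps)
        scaffolded = bool(gaps)
        for span in contigs:
            contig_lengths.append(span.length)
            contig_seqs.append(rec.seq[span.start - 1:span.end])
        if scaffolded:
            n_in_scaffolds += len(contigs)
            bases_in_scaffolded += sum(s.length for s in contigs)
        else:
            n_not_in_scaffolds += len(contigs)
            bases_in_unscaffolded += sum(s.length for s in contigs)

    if not contig_lengths:
        raise ParameterError("assembly contains no contig (all-gap input)")

    total_contig_bases = sum(contig_lengths)
    report = AssemblyReport(
        scaffold=_level_stats(scaffold_lengths, composition(records)),
        contig=_level_stats(contig_lengths, composition(contig_seqs)),
        n_contigs_in_scaffolds=n_in_scaffolds,
        n_contigs_not_in_scaffolds=n_not_in_scaffolds,
        pct_in_scaffolded_contigs=100.0 * bases_in_scaffolded / total_contig_bases,
        pct_in_unscaffolded_contigs=100.0 * bases_in_unscaffolded / total_contig_bases,
        mean_contigs_per_scaffold=round(len(contig_lengths) / len(records), 1),
        mean_gap_length=round(sum(gap_lengths) / len(gap_lengths)) if gap_lengths else 0,
        n_gaps=len(gap_lengths),
        total_gap_length=sum(gap_lengths),
    )
    assert report.scaffold.total_size == total_contig_bases + report.total_gap_length
    return report


def _fmt_int(v: int | float) -> str:
    return f"{v:,}"


def format_report(report: AssemblyReport, min_gap: int = 10) -> str:
    """Plain-text report mirroring the standard Assemblathon table layout."""
    lines: list[str] = []

    def row(label: str, *vals) -> None:
        lines.append("\t".join([label] + [str(v) for v in vals]))

    for level_name, s in (("scaffold", report.scaffold), ("contig", report.contig)):
        cap = level_name.capitalize()
        row(f"Number of {level_name}s", _fmt_int(s.count))
        if level_name == "contig":
            row("Number of contigs in scaffolds",
                _fmt_int(report.n_contigs_in_scaffolds))
            row("Number of contigs not in scaffolds",
                _fmt_int(report.n_contigs_not_in_scaffolds))
        row(f"Total size of {level_name}s", _fmt_int(s.total_size))
        row(f"Longest {level_name}", _fmt_int(s.longest))
        row(f"Shortest {level_name}", _fmt_int(s.shortest))
        for t in SIZE_THRESHOLDS:
            c, p = s.thresholds[t]
            row(f"Number of {level_name}s >{_THRESHOLD_LABELS[t]} nt",
                _fmt_int(c), f"{p:.2f}%")
        row(f"Mean {level_name} size", _fmt_int(s.mean))
        row(f"Median {level_name} size", _fmt_int(s.median))
        for e in s.nx:
            row(f"N{e.x} {level_name} length", _fmt_int(e.n_length),
                f"L{e.x} {level_name} count", _fmt_int(e.l_count))
        for b in "ACGTN":
            c, p = s.composition[b]
            row(f"{cap} %{b}", f"{p:.2f}", f"Number of {b}", _fmt_int(c))
        c, p = s.composition["other"]
        row(f"{cap} %non-ACGTN", f"{p:.2f}")
        row(f"Number of {level_name} non-ACGTN nt", _fmt_int(c))
        if level_name == "scaffold":
            row("Percentage of assembly in scaffolded contigs",
                f"{report.pct_in_scaffolded_contigs:.2f}")
            row("Percentage of assembly in unscaffolded contigs",
                f"{report.pct_in_unscaffolded_contigs:.2f}")
            row("Average number of contigs per scaffold",
                f"{report.mean_contigs_per_scaffold:.1f}")
            row(f"Average length of break (>={min_gap} N) between contigs in scaffold",
                _fmt_int(report.mean_gap_length))
            lines.append("")
    return "\n".join(lines) + "\n"
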