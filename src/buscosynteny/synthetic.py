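"""Paired synthetic genomes with a known fusion/fission/relocation history.

The generator draws an ancestral karyotype — multiple chromosomes of random
uniform A/C/G/T content with embedded N-gap runs and non-overlapping ortholog
placements — then emits genome A as the ancestor and genome B as the ancestor
with an ordered list of events applied:

* fusion — two chromosomes concatenated with a 100-N junction gap (so the
  assembly-statistics engine sees one scaffold of two contigs);
* fission — one chromosome split at a uniform breakpoint that avoids
  orthologs;
* relocation — one ortholog moved to a uniform position on another
  chromosome.

Per-ortholog status noise (Missing / Duplicated / Fragmented) is applied
independently per genome after the events, mimicking per-assembly BUSCO
dropout. Everything is reproducible from the seed; identical configs give
byte-identical outputs.

Default scale emulates a turtle-like karyotype at desk size: 25 ancestral
chromosomes of 80–200 kb carrying 500 orthologs (20 per chromosome).
Sequence content is irrelevant to the synteny method — only coordinates
matter — so lengths are scaled down from the ~100 Mb of real chromosomes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from ._util import ParameterError, atomic_write
from .busco_tables import BuscoRecord
from .fasta_io import SequenceRecord, write_fasta

__all__ = [
    "SimConfig", "SimTruth", "SimPair", "simulate_pair", "write_busco_table",
    "write_outputs", "FUSION_JUNCTION_N",
]

FUSION_JUNCTION_N = 100
_SIM_SCORE = 500.0  # fixed score emitted in synthetic tables


@dataclass(frozen=True)
class SimConfig:
    n_ancestral_chroms: int = 25
    chrom_length_range: tuple[int, int] = (80_000, 200_000)
    n_orthologs: int = 500
    # ordered (type, params) with params None for a random draw:
    # ("fusion", (chrom_i, chrom_j) | None), ("fission", chrom | None),
    # ("relocation", busco_id | None)
    events: tuple = ()
    n_gap_runs_per_chrom: int = 2
    gap_length_range: tuple[int, int] = (10, 100)
    ortholog_length: int = 1_000
    missing_rate: float = 0.0
    duplicate_rate: float = 0.0
    fragment_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "duplicate_rate", "fragment_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        if (self.missing_rate + self.duplicate_rate + self.fragment_rate) > 1.0:
            raise ParameterError("noise rates must sum to <= 1")
        for name in ("chrom_length_range", "gap_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ParameterError(f"{name} must satisfy 0 < min <= max")
        if self.n_ancestral_chroms < 1:
            raise ParameterError("need at least one ancestral chromosome")
        if self.n_orthologs < 2 * self.n_ancestral_chroms:
            raise ParameterError(
                "n_orthologs must be >= 2 x n_ancestral_chroms so that "
                "min_links=2 homology edges are recoverable")


@dataclass
class SimTruth:
    """Ground truth: chromosome maps, true placements, planted events."""

    chrom_lengths_a: dict[str, int]
    chrom_lengths_b: dict[str, int]
    placements_a: dict[str, tuple[str, int, int]]
    placements_b: dict[str, tuple[str, int, int]]
    events: list[dict] = field(default_factory=list)

    @property
    def n_fusions(self) -> int:
        return sum(e["type"] == "fusion" for e in self.events)

    @property
    def n_fissions(self) -> int:
        return sum(e["type"] == "fission" for e in self.events)


@dataclass
class SimPair:
    genome_a: list[SequenceRecord]
    genome_b: list[SequenceRecord]
    table_a: list[BuscoRecord]
    table_b: list[BuscoRecord]
    truth: SimTruth


class _Chrom:
    __slots__ = ("seq", "orthologs")

    def __init__(self, seq: str, orthologs: dict[str, tuple[int, int]]):
        self.seq = seq
        self.orthologs = orthologs  # busco_id -> (start, end), 1-based


_LETTERS = np.frombuffer(b"ACGT", dtype="S1")


def _random_chrom(rng: np.random.Generator, length: int,
                  ortholog_ids: list[str], ortholog_length: int,
                  n_gaps: int, gap_range: tuple[int, int]) -> _Chrom:
    gap_lengths = [int(rng.integers(gap_range[0], gap_range[1] + 1))
                   for _ in range(n_gaps)]
    feat_lengths = [ortholog_length] * len(ortholog_ids) + gap_lengths
    free = length - sum(feat_lengths)
    if free < 0:
        raise ParameterError(
            f"chromosome of length {length} cannot hold "
            f"{len(ortholog_ids)} orthologs + {n_gaps} gaps")
    # uniform non-overlapping placement: cut points partition the free space
    n_feat = len(feat_lengths)
    order = rng.permutation(n_feat)
    cuts = np.sort(rng.integers(0, free + 1, size=n_feat))
    seq_arr = _LETTERS[rng.integers(0, 4, size=length)].copy()
    orthologs: dict[str, tuple[int, int]] = {}
    offset = 0
    for pos, idx in enumerate(order):
        start0 = int(cuts[pos]) + offset       # 0-based
        flen = feat_lengths[idx]
        if idx < len(ortholog_ids):
            orthologs[ortholog_ids[idx]] = (start0 + 1, start0 + flen)
        else:
            seq_arr[start0:start0 + flen] = b"N"
        offset += flen
    return _Chrom(seq_arr.tobytes().decode("ascii"), orthologs)


def _overlaps(start: int, end: int, intervals) -> bool:
    return any(s <= end and start <= e for s, e in intervals)


def _apply_fusion(rng, chroms: dict[str, _Chrom], params, truth_events,
                  counter: list[int]) -> None:
    names = sorted(chroms)
    if params is None:
        if len(names) < 2:
            raise ParameterError("fusion requires >= 2 chromosomes")
        i, j = rng.choice(len(names), size=2, replace=False)
        ni, nj = names[int(i)], names[int(j)]
    else:
        ni, nj = params
        if ni not in chroms or nj not in chroms or ni == nj:
            raise ParameterError(f"fusion of unknown/identical chromosomes "
                                 f"({ni!r}, {nj!r})")
    left, right = chroms.pop(ni), chroms.pop(nj)
    shift = len(left.seq) + FUSION_JUNCTION_N
    merged = dict(left.orthologs)
    merged.update({bid: (s + shift, e + shift)
                   for bid, (s, e) in right.orthologs.items()})
    counter[0] += 1
    new_name = f"B_fusion{counter[0]}"
    chroms[new_name] = _Chrom(
        left.seq + "N" * FUSION_JUNCTION_N + right.seq, merged)
    truth_events.append({"type": "fusion", "chrom_i": ni, "chrom_j": nj,
                         "result": new_name})


def _apply_fission(rng, chroms: dict[str, _Chrom], params, truth_events,
                   counter: list[int]) -> None:
    if params is None:
        names = sorted(chroms)
        name = names[int(rng.integers(len(names)))]
    else:
        name = params
        if name not in chroms:
            raise ParameterError(f"fission of unknown chromosome {name!r}")
    chrom = chroms[name]
    L = len(chrom.seq)
    intervals = list(chrom.orthologs.values())
    for _ in range(100):
        bp = int(rng.integers(1, L))  # split between bp and bp+1 (1-based)
        if not any(s <= bp < e for s, e in intervals):
            break
    else:
        raise ParameterError(
            f"no ortholog-free breakpoint found on {name!r} after 100 tries")
    del chroms[name]
    counter[1] += 1
    na, nb = f"B_fission{counter[1]}a", f"B_fission{counter[1]}b"
    chroms[na] = _Chrom(chrom.seq[:bp],
                        {bid: (s, e) for bid, (s, e) in
                         chrom.orthologs.items() if e <= bp})
    chroms[nb] = _Chrom(chrom.seq[bp:],
                        {bid: (s - bp, e - bp) for bid, (s, e) in
                         chrom.orthologs.items() if s > bp})
    truth_events.append({"type": "fission", "chrom": name,
                         "breakpoint": bp, "results": [na, nb]})


def _apply_relocation(rng, chroms: dict[str, _Chrom], params,
                      truth_events) -> None:
    locations = {bid: name for name in sorted(chroms)
                 for bid in chroms[name].orthologs}
    if params is None:
        ids = sorted(locations)
        bid = ids[int(rng.integers(len(ids)))]
    else:
        bid = params
        if bid not in locations:
            raise ParameterError(f"relocation of unknown ortholog {bid!r}")
    src = locations[bid]
    targets = [n for n in sorted(chroms) if n != src]
    if not targets:
        raise ParameterError("relocation requires >= 2 chromosomes")
    s, e = chroms[src].orthologs[bid]
    flen = e - s + 1
    for _ in range(100):
        tgt = targets[int(rng.integers(len(targets)))]
        tchrom = chroms[tgt]
        if len(tchrom.seq) < flen:
            continue
        start = int(rng.integers(1, len(tchrom.seq) - flen + 2))
        end = start + flen - 1
        if _overlaps(start, end, tchrom.orthologs.values()):
            continue
        if "N" in tchrom.seq[start - 1:end]:
            continue  # do not drop an ortholog into a gap run
        break
    else:
        raise ParameterError(
            f"no collision-free relocation target for {bid!r} after 100 tries")
    del chroms[src].orthologs[bid]
    chroms[tgt].orthologs[bid] = (start, end)
    truth_events.append({"type": "relocation", "busco_id": bid,
                         "from": src, "to": tgt, "start": start, "end": end})


def _noisy_table(rng: np.random.Generator, chroms: dict[str, _Chrom],
                 all_ids: list[str], cfg: SimConfig) -> list[BuscoRecord]:
    placements = {bid: (name, s, e) for name in sorted(chroms)
                  for bid, (s, e) in chroms[name].orthologs.items()}
    records: list[BuscoRecord] = []
    names = sorted(chroms)
    for bid in all_ids:
        u = float(rng.random())
        chrom, s, e = placements[bid]
        if u < cfg.missing_rate:
            records.append(BuscoRecord(busco_id=bid, status="Missing"))
        elif u < cfg.missing_rate + cfg.duplicate_rate:
            records.append(BuscoRecord(
                busco_id=bid, status="Duplicated", scaffold_id=chrom,
                start=s, end=e, score=_SIM_SCORE, length=e - s + 1))
            other = names[int(rng.integers(len(names)))]
            o_len = len(chroms[other].seq)
            flen = min(e - s + 1, o_len)
            o_start = int(rng.integers(1, o_len - flen + 2))
            records.append(BuscoRecord(
                busco_id=bid, status="Duplicated", scaffold_id=other,
                start=o_start, end=o_start + flen - 1, score=_SIM_SCORE,
                length=flen))
        elif u < cfg.missing_rate + cfg.duplicate_rate + cfg.fragment_rate:
            half_end = s + max(0, (e - s) // 2)
            records.append(BuscoRecord(
                busco_id=bid, status="Fragmented", scaffold_id=chrom,
                start=s, end=half_end, score=_SIM_SCORE,
                length=half_end - s + 1))
        else:
            records.append(BuscoRecord(
                busco_id=bid, status="Complete", scaffold_id=chrom,
                start=s, end=e, score=_SIM_SCORE, length=e - s + 1))
    return records


def simulate_pair(config: SimConfig = SimConfig()) -> SimPair:
    """Generate (genome A, genome B, BUSCO table A, BUSCO table B, truth)."""
    rng = np.random.default_rng(config.seed)
    n_chroms = config.n_ancestral_chroms
    width = len(str(n_chroms))
    # distribute orthologs as evenly as possible across chromosomes
    per_chrom = [config.n_orthologs // n_chroms
                 + (1 if i < config.n_orthologs % n_chroms else 0)
                 for i in range(n_chroms)]
    all_ids: list[str] = []
    ancestor: dict[str, _Chrom] = {}
    next_id = 1
    for i in range(n_chroms):
        name = f"chr{i + 1:0{width}d}"
        ids = [f"SCO{j:05d}" for j in range(next_id, next_id + per_chrom[i])]
        next_id += per_chrom[i]
        all_ids.extend(ids)
        length = int(rng.integers(config.chrom_length_range[0],
                                  config.chrom_length_range[1] + 1))
        ancestor[name] = _random_chrom(
            rng, length, ids, config.ortholog_length,
            config.n_gap_runs_per_chrom, config.gap_length_range)

    chroms_a = {f"A_{n}": _Chrom(c.seq, dict(c.orthologs))
                for n, c in ancestor.items()}
    chroms_b = {f"B_{n}": _Chrom(c.seq, dict(c.orthologs))
                for n, c in ancestor.items()}

    truth_events: list[dict] = []
    counter = [0, 0]  # fusions, fissions
    for ev_type, params in config.events:
        if ev_type == "fusion":
            _apply_fusion(rng, chroms_b, params, truth_events, counter)
        elif ev_type == "fission":
            _apply_fission(rng, chroms_b, params, truth_events, counter)
        elif ev_type == "relocation":
            _apply_relocation(rng, chroms_b, params, truth_events)
        else:
            raise ParameterError(f"unknown event type {ev_type!r}")

    truth = SimTruth(
        chrom_lengths_a={n: len(c.seq) for n, c in sorted(chroms_a.items())},
        chrom_lengths_b={n: len(c.seq) for n, c in sorted(chroms_b.items())},
        placements_a={bid: (n, s, e) for n in sorted(chroms_a)
                      for bid, (s, e) in sorted(chroms_a[n].orthologs.items())},
        placements_b={bid: (n, s, e) for n in sorted(chroms_b)
                      for bid, (s, e) in sorted(chroms_b[n].orthologs.items())},
        events=truth_events,
    )
    genome_a = [SequenceRecord(id=n, seq=chroms_a[n].seq)
                for n in sorted(chroms_a)]
    genome_b = [SequenceRecord(id=n, seq=chroms_b[n].seq)
                for n in sorted(chroms_b)]
    table_a = _noisy_table(rng, chroms_a, all_ids, config)
    table_b = _noisy_table(rng, chroms_b, all_ids, config)
    return SimPair(genome_a=genome_a, genome_b=genome_b,
                   table_a=table_a, table_b=table_b, truth=truth)


def write_busco_table(records, path: str | os.PathLike,
                      dialect: str = "v2") -> None:
    """Emit a parseable BUSCO full table (dialect "v2" or "v5").

    ``parse_full_table(write(x))`` reproduces the records (the v5 dialect adds
    an explicit '+' strand column that v2 lacks; strand is not used
    downstream).
    """
    if dialect not in {"v2", "v5"}:
        raise ParameterError(f"dialect must be v2 or v5, got {dialect!r}")
    with atomic_write(path) as fh:
        fh.write("# Synthetic BUSCO full table\n")
        if dialect == "v2":
            fh.write("# Busco id\tStatus\tContig\tStart\tEnd\tScore\tLength\n")
        else:
            fh.write("# Busco id\tStatus\tSequence\tGene Start\tGene End\t"
                     "Strand\tScore\tLength\n")
        for r in records:
            if r.status == "Missing":
                fh.write(f"{r.busco_id}\tMissing\n")
                continue
            fields = [r.busco_id, r.status, r.scaffold_id,
                      str(r.start), str(r.end)]
            if dialect == "v5":
                fields.append(r.strand or "+")
            fields += [f"{r.score:g}" if r.score is not None else "",
                       str(r.length) if r.length is not None else ""]
            fh.write("\t".join(fields) + "\n")


def write_outputs(pair: SimPair, outdir: str | os.PathLike,
                  dialect: str = "v2") -> dict[str, str]:
    """Write FASTAs, BUSCO tables, and the truth JSON into ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome_a": os.path.join(outdir, "genome_A.fasta"),
        "genome_b": os.path.join(outdir, "genome_B.fasta"),
        "table_a": os.path.join(outdir, "busco_A.tsv"),
        "table_b": os.path.join(outdir, "busco_B.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(pair.genome_a, paths["genome_a"])
    write_fasta(pair.genome_b, paths["genome_b"])
    write_busco_table(pair.table_a, paths["table_a"], dialect=dialect)
    write_busco_table(pair.table_b, paths["table_b"], dialect=dialect)
    with atomic_write(paths["truth"]) as fh:
        json.dump(asdict(pair.truth), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
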