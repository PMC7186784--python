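"""Assembly-statistics engine: contig splitting, Nx/Lx, composition, report."""

import pytest
from hypothesis import given, strategies as st

from buscosynteny import ParameterError
from buscosynteny.asmstats import (assembly_report, composition,
                                   format_report, nx_series,
                                   split_into_contigs)
from buscosynteny.fasta_io import SequenceRecord


def brute_force_contigs(seq: str, min_gap: int):
    """Independent oracle: per-position scan marking bases inside long N-runs."""
    in_gap = [False] * len(seq)
    i = 0
    while i < len(seq):
        if seq[i] in "Nn":
            j = i
            while j < len(seq) and seq[j] in "Nn":
                j += 1
            if j - i >= min_gap:
                for k in range(i, j):
                    in_gap[k] = True
            i = j
        else:
            i += 1
    contigs, gaps = [], []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and in_gap[j] == in_gap[i]:
            j += 1
        if in_gap[i]:
            gaps.append(j - i)
        else:
            contigs.append((i + 1, j))
        i = j
    return contigs, gaps


def brute_force_nx(lengths, x):
    """Independent oracle: smallest prefix of the descending sort covering x%."""
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    need = total * x / 100
    running, taken = 0, 0
    while running < need and abs(running - need) > 1e-9:
        running += desc[taken]
        taken += 1
    taken = max(taken, 1)
    return desc[taken - 1], taken


@pytest.mark.parametrize("seq, exp_contigs, exp_gaps", [
    ("ACGT" + "N" * 10 + "ACGT", [(1, 4), (15, 18)], [10]),   # at threshold
    ("ACGT" + "N" * 9 + "ACGT", [(1, 17)], []),               # below threshold
    ("N" * 12 + "ACGT", [(13, 16)], [12]),                    # leading gap
    ("ACGT" + "N" * 12, [(1, 4)], [12]),                      # trailing gap
    ("N" * 15, [], [15]),                                     # all gap
    ("ACGTACGT", [(1, 8)], []),                               # no gap
])
def test_split_into_contigs(seq, exp_contigs, exp_gaps):
    spans, gaps = split_into_contigs(SequenceRecord("s", seq))
    assert [(c.start, c.end) for c in spans] == exp_contigs
    assert gaps == exp_gaps


def test_split_single_run_enumeration():
    """Every placement of one N-run in a 20-base toy matches the per-position
    oracle, confirming contig maximality at the gap threshold."""
    for run_len in range(1, 21):
        for pos in range(0, 21 - run_len):
            seq = "A" * pos + "N" * run_len + "C" * (20 - pos - run_len)
            spans, gaps = split_into_contigs(SequenceRecord("s", seq))
            exp_contigs, exp_gaps = brute_force_contigs(seq, 10)
            assert [(c.start, c.end) for c in spans] == exp_contigs
            assert gaps == exp_gaps


@given(st.text(alphabet="ACGTN", min_size=1, max_size=300),
       st.integers(min_value=1, max_value=12))
def test_split_matches_oracle_and_conserves(seq, min_gap):
    spans, gaps = split_into_contigs(SequenceRecord("s", seq), min_gap=min_gap)
    exp_contigs, exp_gaps = brute_force_contigs(seq, min_gap)
    assert [(c.start, c.end) for c in spans] == exp_contigs
    assert gaps == exp_gaps
    assert sum(c.length for c in spans) + sum(gaps) == len(seq)


def test_split_rejects_bad_min_gap():
    with pytest.raises(ParameterError):
        split_into_contigs(SequenceRecord("s", "ACGT"), min_gap=0)


def test_nx_worked_example():
    series = {e.x: (e.n_length, e.l_count) for e in nx_series([8, 5, 4, 2, 1])}
    assert series[50] == (5, 2)
    assert series[90] == (2, 4)


def test_nx_single_sequence():
    for e in nx_series([10]):
        assert (e.n_length, e.l_count) == (10, 1)


def test_nx_empty_errors():
    with pytest.raises(ParameterError):
        nx_series([])


@given(st.lists(st.integers(min_value=1, max_value=10_000),
                min_size=1, max_size=60))
def test_nx_matches_oracle_and_is_monotone(lengths):
    series = nx_series(lengths)
    for e in series:
        n, l = brute_force_nx(lengths, e.x)
        assert (e.n_length, e.l_count) == (n, l)
    ns = [e.n_length for e in series]
    ls = [e.l_count for e in series]
    assert ns == sorted(ns, reverse=True)
    assert ls == sorted(ls)


@pytest.mark.parametrize("seq, base, exp_count, exp_pct", [
    ("ACGTN", "A", 1, 20.0),
    ("ACGTN", "N", 1, 20.0),
    ("acgt", "A", 1, 25.0),
    ("ACGTRY", "other", 2, 100 / 3),
])
def test_composition(seq, base, exp_count, exp_pct):
    comp = composition([seq])
    assert comp[base][0] == exp_count
    assert comp[base][1] == pytest.approx(exp_pct)


def test_report_single_scaffolded_scaffold():
    rec = SequenceRecord("s1", "AAAA" + "N" * 10 + "CCCC")
    rep = assembly_report([rec])
    assert rep.scaffold.count == 1
    assert rep.contig.count == 2
    assert rep.n_contigs_in_scaffolds == 2
    assert rep.pct_in_scaffolded_contigs == pytest.approx(100.0)
    assert rep.mean_gap_length == 10
    assert rep.contig.composition["N"][0] == 0  # gap Ns excluded from contigs


def test_report_gap_free_scaffolds_are_unscaffolded():
    recs = [SequenceRecord("a", "ACGTAC"), SequenceRecord("b", "ACGT")]
    rep = assembly_report(recs)
    assert rep.contig.count == 2
    assert rep.n_contigs_not_in_scaffolds == 2
    assert rep.pct_in_unscaffolded_contigs == pytest.approx(100.0)
    assert rep.scaffold.median == 4  # lower central value of {4, 6}
    assert rep.scaffold.mean == 5


@given(st.lists(st.text(alphabet="ACGTNacgt", min_size=1, max_size=120),
                min_size=1, max_size=12))
def test_report_conservation_and_partitions(seqs):
    recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
    try:
        rep = assembly_report(recs)
    except ParameterError:  # all-gap assembly has no contig
        assert all(set(s.upper()) <= {"N"} for s in seqs)
        return
    assert (rep.contig.total_size + rep.total_gap_length
            == rep.scaffold.total_size)
    assert (rep.n_contigs_in_scaffolds + rep.n_contigs_not_in_scaffolds
            == rep.contig.count)
    assert rep.pct_in_scaffolded_contigs + rep.pct_in_unscaffolded_contigs \
        == pytest.approx(100.0)
    counts = [rep.scaffold.thresholds[t][0]
              for t in sorted(rep.scaffold.thresholds)]
    assert all(c <= rep.scaffold.count for c in counts)
    assert counts == sorted(counts, reverse=True)


def test_scaffold_stats_agree_with_seqkit(tmp_path, null_pair):
    """Independent cross-check: seqkit computes the same scaffold N50/L50,
    count, and total length on a simulated genome."""
    import csv
    import subprocess
    from buscosynteny.fasta_io import write_fasta
    fa = tmp_path / "g.fa"
    write_fasta(null_pair.genome_a, fa)
    out = subprocess.run(["seqkit", "stats", "-a", "-T", str(fa)],
                         capture_output=True, text=True, check=True)
    row = next(csv.DictReader(out.stdout.splitlines(), delimiter="\t"))
    rep = assembly_report(null_pair.genome_a)
    nx = {e.x: e for e in rep.scaffold.nx}
    assert int(row["num_seqs"]) == rep.scaffold.count
    assert int(row["sum_len"]) == rep.scaffold.total_size
    assert int(row["N50"]) == nx[50].n_length
    assert int(row["N50_num"]) == nx[50].l_count
    assert int(row["max_len"]) == rep.scaffold.longest
    assert int(row["min_len"]) == rep.scaffold.shortest


def test_format_report_layout():
    txt = format_report(assembly_report(
        [SequenceRecord("s", "AAAA" + "N" * 10 + "CCCC")]))
    assert "N50 scaffold length\t18" in txt
    assert "Number of contigs\t2" in txt
    assert "Average length of break (>=10 N) between contigs in scaffold\t10" in txt
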