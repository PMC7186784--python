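# Methods

## The model

The unit of evidence is a single-copy ortholog (SCO): a BUSCO found exactly
once (status Complete) in a genome. If an ortholog is single-copy in two
genomes, its two placements define a synteny link — one conserved locus with
coordinates on a chromosome of each genome. Synteny is used in the sense of
conservation of order of orthologous genes between species, but the event
logic here works at a coarser grain: which chromosome of A carries loci that
chromosome X of B also carries.

Aggregating links by chromosome pair gives a bipartite multigraph whose
edges are weighted by shared-SCO count. Under the assumptions that (i)
interchromosomal exchange is dominated by whole-arm fusions and fissions,
and (ii) single-gene movements are noise, each connected component of this
graph is one cluster of homologous chromosomes, and its shape determines the
minimum rearrangement count:

| shape (|A| : |B|) | classification | events |
|---|---|---|
| 1 : 1 | one_to_one | 0 |
| 1 : b | fusion_in_a (= fission in B's lineage) | b − 1 |
| a : 1 | fission_in_a (= fusion in B's lineage) | a − 1 |
| a : b | complex | ≥ a + b − 2 |

a + b − 2 is provably the minimum number of merge/split operations
transforming a partition with a blocks into one with b blocks when their
union is connected; the test suite confirms this against a breadth-first
search over all small bipartite topologies. Complex components are reported
as lower bounds only — rearrangement history is underdetermined at
chromosome resolution.

Two genomes cannot polarize an event. The report labels all counts
"relative"; `polarize()` optionally uses a third genome: whichever state
(joined or split) the outgroup shares is taken as ancestral, and the event
is assigned to the other lineage's branch (standard three-taxon parsimony).

## Filtering: single relocations

A chromosome pair connected by exactly one shared SCO is a "single
relocation" — most plausibly a tandem duplication/translocation of one gene,
an annotation artifact, or a misassembly, not a chromosomal rearrangement.
`filter_single_relocations` removes links whose pair support is below
`min_links` (default 2, exposed everywhere as `--min-links`). The filter is
applied before graph construction, so a spurious ortholog can never create
or join components. Raising `min_links` never adds edges and never merges
components.

## Reverse-complement merging

Gene predictors are not strand-symmetric: running BUSCO a second time on the
reverse complement of an assembly recovers orthologs missed in the forward
run. A revcomp placement [s, e] on a length-L scaffold is remapped to
forward coordinates as [L − e + 1, L − s + 1] (an involution; interval
length preserved). Per ortholog, the run with the better status wins under
Complete > Duplicated > Fragmented > Missing; on ties the forward record is
kept — a Complete-in-both conflict at different loci has no principled
resolution without a third line of evidence, so the convention favours the
run the assembly was annotated against. Merging can
therefore only increase Complete counts and only decrease Missing counts.

## Assembly statistics

Contigs are maximal scaffold spans free of N-runs of length ≥ `min_gap`
(default 10); shorter N-runs stay inside contigs and are counted in contig
composition. Leading/trailing qualifying runs are gaps that bound no empty
contig. Conservation (Σ contig + Σ gap = Σ scaffold lengths) is asserted on
every report.

Numerical conventions, chosen where the Assemblathon lineage of scripts is
ambiguous and isolated so they can be audited in one place
(`asmstats.py` module docstring):

* Nx = length at which the descending cumulative sum first reaches
  ceil(x% of total), totals including N; ties resolve to the earlier
  (larger-length) rank. Cross-checked against `seqkit stats -a` in the
  tests.
* Means are rounded to the nearest integer (contigs-per-scaffold to one
  decimal); the median of an even count is the lower central value, keeping
  integer output.
* Size-class percentages ("> 1K nt" etc.) are percentages of sequence
  *count*, not bases.
* No minimum contig length: any span ≥ 1 bp counts.
* Composition is case-insensitive (soft-masked assemblies), with percentages
  over all residues including N.

## Synthetic data: what it emulates and what it does not

`simulate_pair` draws an ancestral karyotype and derives genome B by an
ordered event list; genome A is the ancestor. Defaults model a turtle-like
study system at desk scale:

| parameter | default | why |
|---|---|---|
| n_ancestral_chroms | 25 | haploid chromosome count of the focal karyotype |
| n_orthologs | 500 | 20 SCOs per chromosome — enough that every homology edge clears min_links=2 with large margin |
| chrom_length_range | 80–200 kb | scaled from ~20–350 Mb real chromosomes; only coordinates, not content, carry the method |
| ortholog_length | 1 kb | gene-scale interval |
| n_gap_runs_per_chrom, gap_length_range | 2, 10–100 N | exercises the contig splitter on every simulated genome |
| noise rates | 0 | per-ortholog Missing/Duplicated/Fragmented dropout, off by default |

Fusions concatenate two chromosomes with a 100-N junction, so the statistics
engine sees the fused chromosome as one scaffold of two contigs — one
fixture exercises both subsystems. Fission breakpoints avoid orthologs
(100 retries, then a config error). Relocations move one ortholog to a
collision-free position on another chromosome. All randomness flows through
one seeded generator; identical configs give byte-identical outputs.

Deliberately not emulated: sequence evolution (substitutions, repeats,
indels), inversions (orientation is not consumed downstream), assembly
fragmentation, and BUSCO's actual HMM-based detection. Passing tests
therefore demonstrate that the coordinate logic — splitting, remapping,
linking, filtering, component classification — is correct, not that BUSCO
itself places orthologs correctly on real assemblies, and not that real
noise regimes (fragmented assemblies, paralog confusion) are handled beyond
the modelled per-ortholog dropout.

## Problem sizes in the checks

The replicate-based checks run 200 simulated pairs (12 chromosomes × 20
SCOs, 40–80 kb chromosomes) for fusion recovery plus 100 null pairs, 1,000
random multisets for the Nx oracle, 1,000 random scaffolds for conservation,
and 10,000 random intervals for the remapping involution. The acceptance
script's headline pair uses a 27-chromosome ancestor with two fusions —
reproducing, at desk scale, a testudinoid-like 2n contrast in which the
descendant karyotype has 25 chromosomes. These sizes were chosen as the
smallest at which every chromosome still carries enough SCOs for edges to
clear the relocation filter with margin.

## Known limitations

* Polarity requires an outgroup; with two genomes the fusion/fission labels
  are interchangeable readings of the same component.
* Complex (a : b) components are counted as a + b − 2 events, a lower
  bound; no DCJ-style distance is attempted.
* Inversions and intra-chromosomal order are invisible: links carry
  positions but events are called on chromosome membership only.
* Chromosomes with no surviving link are listed as "unlinked", never as
  events — a genome-specific chromosome (e.g. a microchromosome with no
  detected SCO) contributes nothing.
* BUSCO v2 tables lack strand; where a later dialect provides it, strand is
  recorded but unused, matching the position-only links downstream.
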