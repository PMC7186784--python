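# buscosynteny

Comparative genomics of karyotype evolution from BUSCO single-copy orthologs.

Chromosome-level genome assemblies of related species often differ in
chromosome number (2n), and the differences are driven by chromosomal fusions
and fissions. Detecting these events normally requires whole-genome alignment
or full annotation. This package implements a lighter route: the placements of
Benchmarking Universal Single-Copy Orthologs (BUSCOs) — which most assembly
projects already compute for quality assessment — are reused as synteny
anchors. Each ortholog found Complete (single-copy) in two genomes becomes a
synteny "link" between a chromosome of each; the pattern of links reveals how
chromosomes of one karyotype map onto the other.

It is aimed at genome-assembly and comparative-genomics groups who have
chromosome-level FASTA assemblies and BUSCO full tables and want (a)
Assemblathon-style contiguity statistics, (b) Circos-ready synteny input
files, and (c) a count of fusion/fission events between two karyotypes.

## Method

1. **Assembly statistics** — scaffolds are decomposed into contigs at N-runs
   of length ≥ 10 (configurable); the full metric set is computed at both
   levels: counts, total/longest/shortest, size-class counts, mean/median,
   N50–N90 with L50–L90, base composition, gap statistics. Nx is the length
   of the sequence at which the descending cumulative length first reaches
   x% of the total; Lx is its rank.
2. **BUSCO table handling** — full tables (v2–v5 dialects) are parsed;
   a forward run and a reverse-complement run can be merged, remapping
   revcomp coordinates via `[s,e] → [L−e+1, L−s+1]` and keeping, per
   ortholog, the better status (Complete > Duplicated > Fragmented >
   Missing; ties keep the forward record). Complete orthologs form the
   single-copy-ortholog (SCO) set.
3. **Synteny links** — one link per ortholog in both SCO sets. Chromosome
   pairs supported by fewer than `min_links = 2` shared orthologs are
   *single relocations* and are removed: one ortholog cannot evidence a
   rearrangement.
4. **Event detection** — filtered links induce a bipartite graph over the
   chromosomes of the two genomes, edges weighted by shared-SCO count. Each
   connected component is classified: 1:1 (no event), 1:b (b−1 fusion/fission
   events), a:1 (a−1 events), a:b complex (a+b−2 events as a lower bound).
   Polarity (which lineage changed) requires an outgroup; a three-genome
   parsimony helper assigns events to lineages.
5. **Circos export** — karyotype (`chr - ID LABEL 0 END COLOR`) and
   two-segment links files, byte-deterministic.
6. **Simulation** — seeded genome pairs with planted fusion / fission /
   relocation histories and BUSCO-style tables, for validation.

## Worked example

```sh
buscosynteny simulate --seed 7 --chroms 5 --orthologs 100 --fusions 2 \
    --out-dir sim/
buscosynteny synteny --busco-a sim/busco_A.tsv --busco-b sim/busco_B.tsv \
    --out links.tsv
buscosynteny events --links links.tsv
```

prints

```
100 shared SCOs, 100 links kept (min_links=2)
components: 3
  one-to-one: 1
  fusion-in-A events (= fission-in-B): 0
  fission-in-A events (= fusion-in-B): 2
  complex components (event counts are minima): 0
note: event counts are relative between the two genomes; lineage polarity requires an outgroup
```

Genome B was generated from the 5-chromosome ancestor (= genome A) by two
fusions, so B has 3 chromosomes. All 100 orthologs are shared and no
chromosome pair is a singleton, so nothing is filtered. Reading the
components from A's side: two pairs of A chromosomes each cluster onto one
fused B chromosome (one event each, reported as "fission-in-A =
fusion-in-B") and the fifth A chromosome maps 1:1 — exactly the two planted
fusions, recovered from coordinates alone.

Assembly statistics for any FASTA:

```sh
buscosynteny stats sim/genome_B.fasta --json stats.json
```

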