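# retrobench

Structural annotation, insertion dating and cross-assembly tracking of
LTR retrotransposons, plus an assembly-quality benchmark panel — validated
end to end on synthetic genomes with planted ground truth.

Large plant genomes are dominated by LTR retrotransposons whose two long
terminal repeats (LTRs) are identical at insertion and diverge with age.
How well an assembly represents these elements (intact copies, gap-free
LTRs, intact target-site duplications) is a sensitive probe of assembly
quality in the repeat-rich intergenic space. `retrobench` implements that
analysis stack and a simulator that plants elements of known age, position
and structure so every stage can be checked against truth.

## Modules

- `retrobench.genome_model` — sequences, intervals, FASTA/BED/GFF3 IO,
  gap segmentation, Nx statistics, gene-flank gap fraction.
- `retrobench.synthetic_genome` — background simulation, element synthesis
  with age-dependent LTR divergence (per-site rate 1.3e-8/year,
  configurable), insertion with 5-bp target-site duplication, solo-LTRs,
  planted genes, and short-read-style degradation (LTR-targeted N runs,
  collapse of near-identical copies, substitutions, fragmentation) with
  full truth bookkeeping.
- `retrobench.ltr_annotator` — structural detection of full-length
  elements (seed 30, LTR length 100–2,000, separation 3,000–25,000,
  similarity ≥ 85 %, TG…CA termini, 4–20 bp TSD, ±60 bp boundary
  refinement), superfamily classification from internal domain order
  (RLC: INT-RT-RH, RLG: RT-RH-INT, else RLX), stringent quality filter
  (no Ns, bounded tandem content, no gene/duplicated domains), solo-LTR
  discovery and family size-class selection.
- `retrobench.ltr_dating` — Kimura 2-parameter LTR divergence, insertion
  age `d / (2·mu)`, TSD decay arithmetic, canonical 20-mer repetitivity,
  age histograms.
- `retrobench.element_tracking` — junction extraction (terminal 100 bp +
  100 bp flank), junction matching across assembly versions with
  orientation/spacing acceptance, water-style element alignment and the
  1,000-bin normalized SNP/N divergence profile.
- `retrobench.assembly_benchmarks` — stringent transcript completeness,
  in-silico DLE-1 (`CTTAAG`) label maps with DP alignment and label-site
  coverage, scaffold retention filter, HC/LC/REP gene-confidence
  classification, combined benchmark report.

## CLI

```sh
retrobench simulate --seed 1 --out sim/          # genome + truth
retrobench stats sim/genome.fasta                # sizes, N50/N90, gaps
retrobench annotate-ltr sim/genome.fasta --domains sim/domains.tsv
retrobench date elements.gff3 sim/genome.fasta
retrobench track --from a.fasta --to b.fasta --elements a.gff3
retrobench digest sim/genome.fasta --out map.tsv
retrobench benchmark sim/genome.fasta --transcripts t.fasta --map map.tsv
retrobench filter-scaffolds meta.tsv
retrobench classify-genes hits.tsv
```

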