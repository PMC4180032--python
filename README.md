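# peamap

Gene-based SNP discovery, genotyping-array design, recombinant-inbred-line
(RIL) linkage mapping and macrosynteny inference for pea (*Pisum sativum*),
implemented as a reusable, fully tested pipeline with a matched
synthetic-data generator.

## The problem

Pea lacks a reference genome, so genic markers are mined from deep
3′-anchored transcriptome sequencing of a diverse accession panel (cultivars
plus wild relatives), filtered into a fixed-size Illumina GoldenGate oligo
pool assay (OPA), genotyped across several F7 RIL populations, and
integrated into a consensus genetic map that can be compared with the model
legume *Medicago truncatula*. This package re-implements that entire desk
side of the study — everything downstream of read alignment — as a library
of composable stages:

* **`peamap.simulate`** — generates every input the pipeline consumes
  (contigs, per-accession pileups, orthologue/splice tables, RIL genotype
  matrices) with the study's statistical structure, alongside the generating
  truth for recovery tests.
* **`peamap.snp`** — count-threshold SNP calling from pileups. A call is
  *high confidence* iff the site has ≥ 3 aligned reads and ≥ 80 % of them
  carry the called allele; only transitions/transversions are reported
  (indels discarded); per-accession observations merge into a non-redundant
  table with states {ref, alt, het_suspect, below_threshold, missing}.
* **`peamap.design`** — the OPA selection cascade: no flanking SNP within
  60 bp → drop suspected heterozygotes → ≥ 60 bp clearance from contig ends
  and splice sites → best assay-design score per contig → orthologous-gene
  de-duplication → score ≥ 0.4 → cultivar-polymorphic core plus wild-only
  supplement filled by least missing data, with a stage-by-stage
  conservation report.
* **`peamap.ssr`** — perfect microsatellite detection (primitive 2–6 bp
  units, ≥ 5 copies, canonical motifs) and copy-number polymorphism flags.
* **`peamap.linkage` / `peamap.consensus`** — marker QC into
  polymorphic/monomorphic/dominant/failed classes, segregation-distortion
  filtering (χ² = (n_A−n_B)²/(n_A+n_B) > 5 dropped; parental allele
  frequency < 0.1 always dropped), two-point linkage with the selfed-RIL
  correction r = R/(2(1−R)), LOD ≥ 5 grouping, greedy + 2-opt ordering,
  Kosambi distances d = 25 ln((1+2r)/(1−2r)) cM, anchor-based consensus
  integration and 20 cM recombination bins.
* **`peamap.synteny`** — greedy collinear-block detection of the consensus
  map on a model genome (≥ 3 markers, ≤ 1 interloper), correspondence
  tables and Circos link export.

## Worked example

```bash
peamap run --config examples/config.yaml --out demo/
```

simulates a 70-contig, two-population study (seed 1) and runs every stage.
The run prints the stage summary:

```
  simulate: 12 files in 0.62s
  discover: 3 files in 2.1s
  design: 2 files in 0.05s
  ssr: 1 files in 0.02s
  qcmap: 4 files in 0.03s
  consensus: 3 files in 0.02s
  synteny: 3 files in 0.01s
```

`demo/snp_summary.tsv` then reports 837 merged SNPs over 59,015 assayable
bp — one SNP per 235 bp segregating among the cultivars alone versus one
per 71 bp once the two wild accessions are included, with a mean minor
allele frequency of 0.27 and a 1.6:1 transition:transversion ratio — the
wild accessions contribute most of the diversity, as expected for this
panel. `demo/cascade_report.json` accounts for every candidate
(837 → 156 → 113 → 83 → 42 → 42 → 32 through the cascade, then a 15-SNP
cultivar-polymorphic core topped up with 17 wild-only markers), and
`demo/consensus.tsv` and `demo/blocks.tsv` hold the binned consensus map
and its syntenic blocks on the model chromosomes (e.g. the first group maps
inverted onto model chromosome 5 across 8 of its markers).

Each product is a plain TSV/CSV/VCF/FASTA file; `manifest.json` records
checksums so a re-run with the same config and seed reproduces every byte.

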