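# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions. All coordinates are 0-based, half-open.

## SNP calling model

The caller is deliberately a count-threshold rule, not a genotype
likelihood: the study design (one inbred plant per accession, modest 454
depth) makes a simple concordance rule the honest description of the
evidence.

For each accession and site, the alternate allele is the modal
non-reference base (ties broken in base order A<C<G<T). A call is
**high confidence** iff `total_reads >= 3` and
`alt_reads / total_reads >= 0.80`; both boundaries are inclusive on the
confident side, reading the published exclusion rule ("fewer than 3 reads
or under 80 %") as its complement. The concordance denominator is all
aligned reads at the site, not just ref+alt reads. An accession is
**het_suspect** when its reads are neither 100 % ref nor 100 % alt —
residual heterozygosity in nominally inbred material; such sites are
removed during array design because the assay would segregate
unpredictably in RILs. Indel evidence is parsed and discarded
(pyrosequencing homopolymer errors make indels unreliable).

Merging emits one record per (contig, position) that has at least one
confident, non-heterozygous alt call. Accessions disagreeing on the
alternate base mark the site tri-allelic; such sites stay in the table
(flagged, and usable as "flanking variation" for the cascade) but are never
design candidates. How the original pipeline handled multi-allelic sites is
not stated anywhere; exclusion-with-flag is this package's choice. Minor
allele frequency is computed over accessions in a clean ref/alt state.

## Array-design cascade

Stage order follows the published narrative: flanking variation →
heterozygote removal → 60 bp clearance → one SNP per contig → orthologous
position de-duplication → score floor → polymorphism/missing-data panel
assembly. The narrative does not pin down whether clearance preceded
heterozygote removal; the narrative order is adopted and each stage is
independently callable, so any order can be composed. Every stage is a pure
filter (output ⊆ input, idempotent), so the accounting report's
`input − removed = output` always reconciles and a second pass is a no-op.

Parameter notes:

* `flank_window_bp = 60`, `min_clearance_bp = 60` (bp): the GoldenGate
  probe-design constraint. Clearance keeps candidates *at* 60 bp (the
  published rule states the removal side, "< 60 bp").
* `min_design_score = 0.4`, preferred ≥ 0.6 (unitless, in [0,1]): the
  assay-design-tool score is an opaque vendor quantity; it is an *input*
  column here (the generator draws it Uniform(0,1)), never computed from
  sequence.
* `max_missing = 4` accessions: the published account quantifies the
  missing-data cap only for the wild-only supplement ("up to four genotypes
  with missing data"); the same cap is applied to the 138-style removal of
  cultivar-polymorphic candidates with "large amounts" of missing data,
  exposed as one knob.
* Polymorphism classes: *cultivar_polymorphic* = at least one cultivar alt
  and one cultivar ref; *wild_only* = cultivars uniform and at least one
  wild accession alt. The supplement fills by (fewest missing, highest
  score), so a candidate missing in one accession always beats one missing
  in three.
* De-duplication keys on the orthologous gene interval
  (chrom:start-end), not basewise model coordinates; unannotated contigs
  never collide.

## SSR detection

Perfect tandem repeats of primitive units of 2–6 bp with ≥ 5 copies,
replacing an external repeat finder whose exact thresholds are not
published; these defaults are exposed in the API. Homopolymers are excluded
(unit ≥ 2 and primitivity), reflecting their unreliability in
pyrosequencing data. Overlapping candidate runs resolve deterministically:
longest total length, then smallest unit, then leftmost. Reported motifs
are canonical (lexicographically least over rotations and their reverse
complements), so a locus names identically from either strand; intervals
on the reverse strand may shift by less than one unit when equal-length
phase-shifted runs tie (ties break leftmost, which is rightmost after
reverse complementing). A locus is copy-number polymorphic when at least
two accessions with data disagree on the copy estimate; with fewer than two
informative accessions the flag is missing, never false.

## RIL genetics

**Two-point.** Lines informative for a pair are those with homozygous calls
at both markers; heterozygous (residual F7) and unknown calls are excluded
pairwise. The observed recombinant fraction between inbred lines, R = k/n,
is converted to the per-meiosis fraction with the standard selfed-RIL
relation r = R/(2(1−R)), capped at 0.5; the published mapping protocol is
silent on this step, but it is the standard treatment for selfing-derived
RILs and matches the generator exactly. LOD is the log10 likelihood ratio
of R̂ against R = 0.5, so a zero-recombinant pair scores n·log10 2.

**QC classes.** Each marker gets exactly one class per population:
*failed* (missing rate > 0.9 or both parents unscored), *dominant* (parents
differ with one unscored and only one homozygous allele appears in the
progeny — the published data's dominant calls, 7–49 per population, are not
operationalized anywhere, so this definition is the package's and is
flagged in output), *monomorphic* (parents identical, progeny uniform),
else *polymorphic*. The distortion χ² uses homozygous calls only, df = 1
against 1:1. Markers with χ² > 5 are dropped unless the population carries
the interspecific-cross override (a per-population boolean, default off);
parental allele frequency < 0.1 ("extreme" distortion) is dropped
unconditionally, override or not. Frequencies in [0.1, 0.3) are classed
*distorted*, ≥ 0.3 *balanced*.

**Grouping and ordering.** Groups are connected components of the graph
joining pairs with LOD ≥ 5 and r̂ < 0.5 (networkx), numbered by size then
lexically smallest member. Interactive ML/regression ordering from the
original software is proprietary and unstated; it is replaced by a stated
deterministic heuristic — seed with the globally closest pair, extend the
chain at whichever end is nearer to the closest unplaced marker, then 2-opt
(first-improvement segment reversals) until no reversal lowers the sum of
adjacent r̂. Positions are cumulative Kosambi distances,
d = 25·ln((1+2r)/(1−2r)) cM. At the simulated densities (~4 cM spacing,
150–200 lines) this recovers true orders exactly up to reversal; it is a
heuristic, and at much sparser or noisier densities ordering errors are
possible.

**Consensus.** The reference frame is the population map carrying the
anchor (framework) markers. Each other group is matched to the reference
group sharing the most markers (at least two required, else it is reported
unplaced), oriented by the sign of the Spearman correlation over shared
markers, and projected by piecewise-linear interpolation between shared
markers with terminal-slope extrapolation — a transparent reinterpretation
of black-box "join groups" map integration. A marker mapped in several
populations takes the mean projected position; groups are shifted to start
at 0. Because each projection is monotone, integration preserves each
population's marker order within segments; disagreement between populations
surfaces as small rank inversions rather than hard failures. Bins are
half-open 20 cM intervals from the group origin, bin = floor(position/20).

## Synteny blocks

A block grows along a linkage group while successive orthologue hits stay
on one model chromosome and move monotonically in the direction set by the
block's first two distinct positions. One interloper per block (default)
may be skipped when the very next hit resumes the pattern; otherwise the
block closes. Blocks need ≥ 3 markers; orientation is the sign of the
Spearman correlation of map order against model positions. The published
study never formalizes a block definition; these defaults are the
package's, exposed in the API. The correspondence table lists model
chromosomes carrying ≥ 20 % of a group's block markers (the threshold
behind multi-chromosome rows is likewise unstated; 20 % is a declared
choice), and the two-species comparison joins block model-interval
intersections transitively through the model genome.

## Synthetic data: what it emulates, and what it does not

One seeded NumPy Generator drives everything; identical seeds reproduce
every output byte for byte.

* **Contigs**: uniform base composition, lengths uniform in 200–1500 bp.
  Real 3′-UTR-biased composition, expression-dependent contig redundancy
  and assembly artefacts are not modelled.
* **Variants**: two site classes — shared sites (each accession alt with
  probability ½) at a union rate giving each cultivar its configured
  1/667 bp density against the reference, and wild-only sites topping wild
  accessions up to 1/99 bp (carrier probability 0.8). Substitutions draw
  transitions with probability 0.64, matching the ratios seen in comparable
  transcriptome studies. Residual heterozygosity converts a carrier to het
  with probability 0.02 per site (~11 % of multi-accession sites show a het
  signature somewhere, consistent with the scale of heterozygote removal in
  the real cascade). Designated marker contigs get one guaranteed clean
  cultivar-polymorphic site at their centre so the map stages have material
  at desk scale; these salt the per-accession density slightly upward.
* **Pileups**: depth Poisson(6) per site; each read reports the haplotype
  allele (het sites draw each read's haplotype fairly) and is miscalled to
  a uniform other base with probability 0.01. No homopolymer-length errors,
  no mapping bias, no FASTQ level simulation.
* **RIL genotypes**: drawn directly from the selfed-RIL mapping function
  R = 2r/(1+2r) as a Markov chain along each group (r from inverse Kosambi
  of the truth gaps) rather than simulating seven explicit selfing
  generations — the exact target distribution, testable in closed form.
  There is no crossover interference beyond the Kosambi convention, and
  linkage groups are independent. Residual heterozygosity is (1/2)^6 per
  locus per line (the F7 expectation from an F1 heterozygote), missing
  calls 3 %, whole-assay failures 7 % (within the observed 6–9 %).
  Distortion is post-meiosis viability selection: lines carrying the B
  allele at a distorted marker survive with probability 1−s, implemented by
  rejection sampling per linkage group (identical to whole-line rejection
  because groups are independent), so linked hitchhiking arises naturally.
  Defaults: 2 % of markers distorted at s = 0.5 — matching the handful of
  distorted loci per cultivated cross rather than the extreme interspecific
  cross, which can be emulated by raising both knobs.
* **Population masks**: each cross segregates at a random subset of markers
  (40 % by default; 80 % for the anchor-carrying reference population),
  mirroring the observed 22–61 % polymorphism range. Masked markers are
  monomorphic, not absent, so QC sees them.
* **Synteny layout**: each linkage group is collinear with one model
  chromosome (random orientation) and non-marker contigs are annotated with
  probability 0.76 at random model positions; real data's partial hits,
  paralogy and UTR-alignment failures are not modelled.

Consequently, passing tests show the *algorithms* recover what the
generative model puts in (rates, orders, rearrangements, distortion); they
do not certify performance on real 454 data with homopolymer errors,
chimeric contigs or cross-species alignment noise.

## Numerical conventions and degenerate inputs

* Kosambi forward/inverse are exact inverses (r = tanh(d/50)/2); the
  forward function rejects r ≥ 0.5, the inverse rejects negative distances.
* LOD uses the 0·log 0 = 0 convention; pairs with fewer than 20 informative
  lines are not estimated.
* Ties break deterministically everywhere: base order A<C<G<T for modal
  alleles, (score, position, base) in the cascade, lexical marker ids in
  grouping/ordering, stable mergesort throughout.
* Degenerate inputs fail loudly: empty genotype matrices, unknown contigs,
  conflicting reference alleles and non-monotone truth maps raise;
  non-ACGT reference bases are skipped with a warning; an unattainable
  panel size yields a partial panel plus a warning, never silence.
* The acceptance script scales the study to 210 contigs and populations of
  90–144 lines, sizes at which every stage's behaviour is measurable in
  seconds while preserving the study's structure (7 linkage groups,
  7 non-reference accessions, 5 populations).
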