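# Methods

`poolcall` reimplements, as a tested library, the analysis stack used to
screen disease-gene panels by sequencing PCR amplicons from several
patients pooled in one non-barcoded library.  This note documents the
models, the parameters that matter, what the synthetic data does and does
not emulate, and the design choices made where the design was genuinely
open.

## The pooled calling model

A pool of N diploid samples contains 2N chromosomes.  A variant carried by
a single heterozygote appears among the reads covering its position at an
expected allele fraction of 1/(2N) — 6.25% for N = 8 — which is close
enough to the raw short-read error rate (~1% at Q20) that single-sample
calling logic does not transfer.  The caller therefore compares, at every
targeted position and for every supported alternate symbol, two
hypotheses:

* **errors only**: every non-reference observation is a sequencing error;
* **variant at frequency f = k/(2N)** for some integer allele count
  k in 1..2N.

With per-entry error probabilities `e_i = 10^(-q_i/10)` from recalibrated
qualities, each observation emits

    p(b | a) = 1 - e_i   if b = a,   else e_i / 3,

giving `L0 = prod_i p(b_i | ref)` and
`L1(k) = prod_i [(1-f) p(b_i | ref) + f p(b_i | alt)]`.  The calling
statistic is `LLR = log10(max_k L1(k) / L0)`, evaluated in log space; a
candidate requires LLR **strictly above** 3 (a likelihood ratio of about
1000).  Log base 10 is a design choice — the threshold's printed value is
consistent with that convention and with the per-strand "above 3" rule.

The allele fraction is then re-estimated by EM on the mixture weight
(E-step: posterior responsibility of the alt component per entry; M-step:
their mean; start at max(1/2N, observed alt fraction); tolerance 1e-8,
cap 200 iterations), and the integer `k_hat` is the argmax of L1 over the
k grid with ties toward smaller k.  **Allele count, not carrier count**:
a homozygote contributes two chromosomes, and without barcodes the data
cannot distinguish one homozygote from two heterozygotes, so the package
reports k rather than a number of samples.  In the emulated homozygote
scenario `k_hat = 2` is the observable signature.

### High-confidence filters

A candidate is promoted to the high-confidence tier only if it

1. shows statistically balanced alt support across strands — a two-sided
   Fisher exact test on [[alt+, ref+], [alt-, ref-]] with p > 0.05.  The
   test is a stand-in for an unspecified "statistically indistinguishable"
   rule; a strand with zero depth is untestable and passes with p = 1 and
   a logged flag.  Note the test has, by construction, a ~5% false-fail
   rate on genuine variants.
2. clears the LLR threshold on the forward strand alone **and** the
   reverse strand alone.  The stricter "both strands > 3" form is the
   default (`both_strand_rule="threshold"`); merely-positive per-strand
   LLRs can be selected by configuration.
3. has no other candidate within 1 bp (adjacency window); both members of
   an adjacent pair fail.

### Indel re-check

Reads that span a large indel may align convincingly on one side only, so
indel evidence is often strand-asymmetric and criterion 2 systematically
rejects it.  The re-check pass scans **all scored** insertion/deletion
alleles and emits those whose LLR exceeds the threshold on either strand
alone into a separate `indel_recheck` tier (VCF filter
`one_strand_indel`).  SNVs are never re-checked.

### Indel representation and left-alignment

Gap evidence is stored VCF-style (anchor base plus inserted/deleted
bases) and normalised to the leftmost equivalent representation before
any aggregation or comparison.  Two places depend on this:

* **Pileup construction.**  Inside a repeat, equivalent gap placements
  chosen by the mapper land at different offsets read by read; without
  normalisation the evidence scatters over many columns and no single
  column reaches the threshold.  Deletion evidence is pooled at the
  canonical first deleted base, insertion evidence at the canonical
  anchor (a read that does not span the canonical anchor carries its
  insertion on a base-less entry that participates only in
  insertion-allele scoring).
* **Reporting.**  A 1 bp deletion planted at the rightmost C of a CCCC
  homopolymer is reported three bases to the left of the planted
  coordinate; a 3 bp duplication in a five-codon GGC run surfaces at the
  run's start.  Calls and truth are therefore compared after
  left-aligning both sides.

## Mapping

The mapper is a deliberate simplification of a quality-aware short-read
aligner, keeping exactly the two parameters that matter downstream: a
mismatch-quality-sum acceptance threshold (`e_max`, default 100) and a
maximal proper-pair outer distance (default 500).  Candidate placements
come from exact 12-mer seeds at either read end on both strands; the
unique placement minimising the sum of qualities at mismatching bases is
accepted if the sum is at most `e_max`; ties at distinct positions leave
the read unmapped (ambiguity is discarded, conservatively).  MAPQ is a
coarse 0/60.  The mapping-quality model, multi-mismatch seeding and
Smith–Waterman rescue of production aligners are intentionally absent —
the original study used its aligner as a black box.

A single-gap fallback handles short indels: one insertion or deletion of
1..`g_max` (default 10) bases at any offset, requiring `anchor_min`
(default 8) exactly matching bases on each flank; the search is
exhaustive (32 bp reads make it cheap) and among equal-scoring placements
at one position the leftmost gap offset wins.  The consequence the
package must surface rather than hide: a 20 bp deletion inside a 32 bp
read leaves at most 12 bp on one side, so no admissible gapped placement
exists, junction reads either die on mismatch-quality-sum or map
ungapped without gap evidence, and the variant becomes a false negative
recorded in the manifest with reason `unmapped-indel`.  This emerges
from the generator + mapper interaction; nothing is special-cased.

## Quality recalibration

Aligned bases are binned by (reported quality, machine cycle 1..32,
preceding called base with a distinguished start-of-read symbol) — the
"preceding nucleotide" axis is interpreted as the dinucleotide context on
the read strand.  Empirical mismatch rates are measured against the
reference at positions absent from the known-sites database (so common
polymorphism does not inflate error estimates), excluding bases within
1 bp of a gap in the same read.  Each bin with at least `min_obs = 100`
observations is assigned `Q = round(-10 log10((mis+1)/(obs+2)))` — add-one
/ add-two smoothing keeps zero-mismatch bins finite — capped at 40;
sparse bins keep their reported quality.  Bases with recalibrated Q
below 20 are dropped from all pileups (Q exactly 20 is kept).  Masking
happens after mapping and before pileup, matching the stage order of the
analysis the package reimplements.

## The synthetic data

The generator emulates the study design: two pools (8 and 7 diploid
samples) sequenced as 32 bp paired-end reads over PCR amplicons at equal
representation.  Specifics:

* **Amplicons** are targets extended by a primer flank (default 200 bp,
  chosen larger than the insert so every target base is reachable by
  reads of both orientations); fragment counts per amplicon are Poisson
  around a common per-base depth; fragment length is normal (150 ± 15,
  comfortably below the 500 bp proper-pair bound); each fragment draws
  its chromosome uniformly from the 2N in the pool, so planted allele
  fractions converge to k/(2N).
* **Haplotypes** carrying indels contribute reads with the alternate
  sequence literally; their mappability is decided downstream.
* **Errors** are substitutions with a true rate rising linearly along the
  read from 0.3% to 1.7% (overall ~1%, the raw Q20-grade error rate of
  the platform), modulated by the preceding template base.  Reported
  qualities match the truth except in the last quarter of the read, where
  they over-report by 4 — the classic overconfident late-cycle pattern
  the recalibrator exists to correct.  Indel sequencing errors, PCR
  duplicates, chimeras and primer read-through are not modelled.
* **Strand bias for indels**: optionally, the read covering an indel
  junction is forced onto the forward strand with a configurable
  probability (1.0 in the second pool's scenario), modelling the
  strand-asymmetric support of larger indels that motivates the re-check
  pass.
* The built-in example panel is deterministic: four toy genes including a
  SOX2-like CDS with a five-codon GGC run (codons 19–23) and a CCCC
  homopolymer at c.536–539, an OTX2-like minus-strand gene, a FOXE3-like
  gene, and a PAX2-like target of which one "exon" is dropped from the
  library to exercise the uncovered-target report.

Passing tests on these data show that the inference, filtering and
bookkeeping behave as specified under the stated noise model; they do not
show robustness to real-data pathologies the generator omits (PCR
artefacts, mapping bias from paralogy, indel sequencing errors,
non-uniform pooling).

### Problem sizes used by the tests and the acceptance script

Column-level experiments (detection power, homozygote recovery,
specificity) run on directly simulated Q20 pileup columns — the same
allele-sampling model collapsed onto one position — at 600X (300 per
strand) for the power scenarios, reflecting the deep per-base coverage of
pooled amplicon libraries, and at exactly 160X for the variant-free
specificity scan, the pool-of-8 completeness floor.  The specificity scan
materialises only columns with at least 4 error observations: at uniform
Q20 evidence and these depths, fewer than four supporting bases cannot
push the LLR above 3, so quieter positions cannot change the call set.
Full-pipeline scenario runs use the example panel at 800X raw amplicon
depth (roughly 500X surviving the Q20 mask).  Coverage completeness in
those runs is 92.9%: every sequenced target is complete and the
deliberately dropped exon (150 of 2100 targeted bases) is reported
uncovered.

## Numerical and policy choices

* Likelihoods in log10 space; per-base error floored at 1e-10.
* Tri-allelic columns report only the best alt (lexicographic tie-break,
  logged); the model is biallelic.
* Gap symbols borrow the flanking base's quality as a proxy error rate
  (no indel error model is specified anywhere upstream).
* EM non-convergence returns the last iterate with a logged flag.
* Known-site triage matching is allele-exact: a novel alternate allele at
  a known SNP position still needs verification.  Database-member calls
  are accepted without verification; the coverage report carries a note
  flagging that policy.
* Completeness uses strict "depth > 20 N", so a base at exactly the
  threshold counts as incomplete.
* One seed drives a run; stages fork named substreams
  (`numpy.random.SeedSequence.spawn`), so reruns are byte-identical.

## Known limitations

* The mapper's tie-discard and minimal seeding under-map repetitive
  references relative to production aligners; mapping qualities are not
  calibrated.
* Carrier *samples* are not estimated (unidentifiable without barcodes);
  `k_hat` saturates near the detection ceiling for large k.
* In homopolymer contexts roughly half of a deletion's spanning reads map
  ungapped (the shifted tail still matches), diluting the apparent indel
  fraction below k/(2N); small-indel LLRs are accordingly conservative
  and may fall to the re-check tier even without strand bias.
* Effect annotation covers simple toy gene models; splice-region effects,
  UTR/intron nomenclature and multi-variant haplotypes are out of scope.
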