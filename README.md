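# poolcall

Variant discovery in **non-barcoded pooled amplicon resequencing** — a
reusable, tested implementation of the analysis stack used to screen
candidate disease genes by sequencing PCR amplicons from several patients
mixed in one library.

When N diploid samples are pooled without barcodes, a mutation carried by
one heterozygote is present on 1 of 2N chromosomes, so its reads appear
at an expected fraction of 1/(2N) — about 6% in a pool of 8 — uncomfortably
close to the raw sequencing error rate (~1% at Q20).  `poolcall`
implements the statistical machinery that makes such calls anyway, plus
everything around it:

* **`poolcall.simulate`** — synthetic pooled paired-end reads (32 bp by
  default) over a target panel with planted SNVs and indels, a
  cycle/context-structured error model with deliberately miscalibrated
  reported qualities, and a truth VCF;
* **`poolcall.mapper`** — a simplified quality-aware short-read mapper:
  ungapped placement scored by the sum of mismatching base qualities
  (threshold 100), paired outer-distance constraint (500), and a
  single-gap fallback for indels up to 10 bp;
* **`poolcall.recal`** — empirical base-quality recalibration binned by
  (reported Q, machine cycle, preceding base) at non-known-variant
  positions, followed by Q20 masking;
* **`poolcall.caller`** — the core: per-position likelihood-ratio test of
  *variant at frequency k/(2N)* against *errors only*, called where
  log10 LLR > 3; EM estimation of the pooled allele count `k_hat`;
  high-confidence filtering (Fisher strand balance, per-strand LLR > 3 on
  both strands, no adjacent candidate); a relaxed either-strand re-check
  for indels; left-alignment of indel calls;
* **`poolcall.report`** — coverage completeness against the 20×N rule
  (> 160X for 8 samples, > 140X for 7), triage of calls into known
  polymorphisms vs a Sanger-style verification list, and coding-effect
  annotation (c./p. notation, nonsense/frameshift/stop-loss classes);
* **`poolcall.pipeline`** — one-seed end-to-end orchestration with a
  machine-readable manifest that classifies every planted variant as
  detected (by tier) or missed (with a reason: `unmapped-indel`,
  `filtered-strand`, `below-LLR`).

See `docs/methods.md` for the model, its assumptions and limitations.

## Worked example

The built-in scenario mirrors a two-pool study design.  The second pool
(7 samples) plants a homozygous nonsense SNV in one sample, a 3 bp GGC
duplication inside a five-codon glycine run with fully strand-biased
support, a 20 bp deletion, and a known SNP:

```bash
poolcall example --pool POOL2 --seed 1 --out-dir results/pool2
```

prints, after simulating ~37,000 read pairs, mapping, recalibrating and
calling:

```
FOXE3L:c.720C>A hom: detected high_confidence
SOX2L:c.64_66dupGGC: detected indel_recheck
SOX2L:c.70del20: missed unmapped-indel
SOX2L:c.300 known SNP: detected high_confidence
```

Reading those four lines:

* the **homozygote** is a high-confidence call with `AC=2` in the VCF —
  the EM correctly reports two variant chromosomes in the pool;
* the **3 bp duplication** is absent from the high-confidence tier
  (its support sits on one strand, so the both-strand LLR rule rejects
  it) but is recovered by the either-strand indel re-check, left-aligned
  to the start of the GGC run (VCF filter `one_strand_indel`);
* the **20 bp deletion** is a false negative: in a 32 bp read the gap
  leaves too little flanking homology, no read maps with the deletion,
  and the manifest says exactly that (`unmapped-indel`);
* the **known SNP** is called and triaged as a database member, so it is
  excluded from the verification list.

The run directory also contains the FASTQ/SAM/VCF intermediates, the
recalibration table, a coverage report (92.9% of targeted bases above
140X — everything except a deliberately dropped exon, which is listed by
name as uncovered), and `manifest.json` with the full truth comparison.

Library use mirrors the CLI:

```python
from poolcall.pipeline import example_run_config, run_pipeline
manifest = run_pipeline(example_run_config("POOL2", seed=1), "results/pool2")
```

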