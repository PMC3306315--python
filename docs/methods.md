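# Methods

`vascde` implements a classic count-based bulk RNA-seq differential-expression
analysis of the kind used to profile a transcription-factor overexpression
contrast against uninjected controls (the motivating study compared zebrafish
embryos overexpressing the ETS-family factor etsrp/etv2 with controls, mapping
reads to a unigene-style transcript database). Every stage is exercised on
synthetic data with known ground truth; no external downloads are needed.

## The statistical model

Let `a` be a gene's pooled uniquely-mapped read(-pair) count in the control
condition, `c` in the overexpression condition, and `N_c`, `N_o` the pooled
mapped totals. Each gene is tested with the two-sided Fisher's exact test on

```
            gene     all other reads
control      a         N_c − a
oe           c         N_o − c
```

using the probability-mass rule: with all margins fixed, the p-value is the
sum of hypergeometric probabilities of every table whose probability does not
exceed the observed table's. A table counts as a tie when
`pmf(x) ≤ pmf(obs)·(1 + 1e-7)`, the convention widely used by statistical
software for this rule; the tolerance makes exact rational ties robust to
floating-point rounding. The computation runs entirely in log space
(`gammaln` + `logsumexp`), so library totals of ~10⁷ are safe; the sum runs
over the hypergeometric support, whose size is bounded by the gene's total
count, not the library size.

P-values are adjusted with the Benjamini–Hochberg step-up procedure:
`q(i) = min_{j≥i} min(1, m·p(j)/j)` over the ascending p-values, returned in
input order. Note the step-up map is *not* idempotent in general
(`[1.0, 0.25] → [1.0, 0.5] → [1.0, 1.0]`); the implementation is instead
validated against an independent literal step-up oracle and statsmodels'
`fdr_bh`.

Fold changes are ratios of library-size-normalized counts (CPM; RPKM ratios
are identical because the gene length cancels):
`fc = ((c + ½·[c=0])/N_o) / ((a + ½·[a=0])/N_c)`. The 0.5 pseudocount is
applied only to zero cells — never to the test, which requires raw integers —
so observed large inductions (a gene absent in controls) stay finite without
shrinking non-zero estimates. A gene is called `up` when `q < 0.05` and
`fc ≥ 1.9`, `down` when `q < 0.05` and `fc ≤ 1/1.9`; both thresholds are
configurable and default to the motivating study's cutoffs.

The multiple-testing family is all genes with a pooled count ≥ 1 in either
condition. All-zero genes carry p = 1 and no information; keeping them would
only inflate `m`. This is an interpretation (the source analysis does not
state its family), exposed by construction rather than a flag.

Fisher's exact test on pooled counts is exact under independent
Poisson/binomial sampling of reads and therefore models *technical* counting
noise only. It has no between-replicate dispersion term; lanes within a
condition are pooled by summation before testing (a `--per-lane`-style
diagnostic is available by simply not pooling). Modern replicate-aware
negative-binomial methods are deliberately out of scope: the package
reproduces the pooled-contrast methodology faithfully.

## Alignment and unique-mapping resolution

Reads are placed ungapped at every offset of every transcript, on both
strands, keeping placements with Hamming distance ≤ 4 (configurable). An `N`
counts as a mismatch to everything. This deliberately simplifies a gapped
short-read aligner (no indels, no quality-aware scoring); the downstream
statistics consume only resolved gene-level assignments. The search is
pigeonhole seed-and-extend — the read is split into `max_mismatch + 1`
disjoint seeds, so every qualifying placement matches at least one seed
exactly; candidates from a k-mer index are verified by full comparison. It is
provably exhaustive and is property-tested against a naive scan of every
offset.

Resolution rules:

* Only the minimal-mismatch stratum is considered; a strictly better hit
  suppresses worse ones (best-hit convention; the source analysis is silent).
* Single-end: unique iff exactly one placement survives. Uniqueness is at the
  *location* level — two tied placements within one gene are ambiguous — with
  a `gene` scope option that collapses within-gene ties.
* Paired-end: every combination of the two mates' placements is examined; a
  combination is correctly paired iff both mates lie on the same gene, on
  opposite strands, with the forward-strand mate upstream (FR orientation).
  No insert-size window is enforced beyond same-transcript bounds. The pair
  is uniquely mapped iff exactly one correctly-paired combination survives in
  the minimal total-mismatch stratum; ambiguous if several; unmapped if none.

Counting: each unique assignment increments its gene by 1 (a pair counts
once). `mapped_total` defaults to the number of unique assignments (the base
the counts live in); `all-mapped` (unique + ambiguous) is available because
"total mapped reads" is ambiguous in the source description.
`RPKM = 10⁹·count/(length·total)`; CPM = `10⁶·count/total`.

## Synthetic data

The generator emulates the study conditions, not real zebrafish libraries:

* **Transcriptome** — i.i.d. uniform ACGT sequences (default 500–1000 bp)
  with engineered identical segments copied between designated gene pairs.
  These shared segments are the *only* homology, giving an exact ground truth
  for which reads are inherently multi-mapping. Real transcriptomes have
  paralog families, repeats and biased composition; passing tests show the
  resolution logic is correct, not that a real unigene build has few
  multi-mappers.
* **Reads** — fixed-length substrings (default 76 bp), unstranded; paired
  mode draws a fragment (default insert 200 bp) and emits FR mates with the
  minus-strand mate reverse-complemented. Substitution errors are planted
  i.i.d. per base; no indels, no quality model (constant Phred+33 `I`), no
  GC or positional bias, no fragment-length distribution.
* **Counts** — per-lane independent Poisson draws. Per-gene baselines are
  log-normal (σ = 1) relative weights, rescaled so each condition's expected
  total equals the configured depth (a sequencer delivers fixed depth; the
  alternative of letting condition B's total drift with the spike mass
  changes only the normalization constant). A gamma-mixing dispersion knob
  exists but defaults off, because the Fisher-on-pooled-counts test is exact
  precisely under the Poisson model. The source analysis never states its
  noise assumptions; Poisson is this package's choice.
* **True fold grid** — the default spike grid {1, 1.9, 4, 32, 250, 1900}
  spans the observed induction range of the motivating dataset (≈2× to
  ≈2000×).

## Validation experiments and their sizes

Chosen as the package's own standard checks (all seeded, all text-only):

* Fisher vs exact-rational enumeration (`fractions.Fraction`, same tie rule
  evaluated exactly): 10,000 random tables with margins ≤ 30; observed
  agreement ~5·10⁻¹⁴ relative.
* BH vs a literal step-up oracle: 1,000 vectors, lengths 1–5,000 (sorted
  uniform draws), absolute agreement at 10⁻¹⁵.
* Null FDR: 50 all-null simulations, 2,000 genes, 10⁵ fragments/condition;
  the empirical false-discovery proportion of the default calling stays at or
  below the nominal 5%.
* Spike recovery: 2,000 genes, 10⁶ fragments/condition, 20 replicates, one
  spike per fold {1.9, 4, 32, 250, 1900} at control baselines {300, 100, 30,
  20, 20} CPM. Baselines were sized by a Poisson power analysis: small folds
  need high baselines for detection, large folds need low baselines so the
  spikes stay a small fraction of the library (total spike mass ≈4.5% of the
  oe library). Success = called `up` with estimated fold within 2× of truth.
* Pair resolution vs exhaustive combination enumeration: 10,000 random mate
  hit-lists (≤ 6 hits per mate); plus 100% unique-and-correct resolution of
  error-free pairs whose origin avoids shared segments.

A known boundary effect, worth stating precisely: a spike whose true fold
*equals* the 1.9 calling threshold is recovered in only ~¼ of replicates.
The fold estimate is unbiased around `1.9/κ` where `κ ≈ 1.045` is the
relative-abundance normalization constant induced by the other spikes, so
the estimate falls below the threshold in more than half of replicates no
matter the depth or baseline. This is a property of thresholding at the true
effect size, not an implementation defect; the corresponding acceptance test
is left failing by design, and power is monotone in the true fold as
expected.

## Numerical and design notes

* Determinism: every stage takes an explicit seed; the pipeline derives all
  stage seeds from one run seed via `SeedSequence` spawning, and repeated
  runs write byte-identical files (logs carry no timestamps).
* Coordinates are 0-based half-open internally, 1-based on SAM I/O (handled
  by pysam). FLAG bits encode strand and mate; NM carries mismatch counts.
* Degenerate inputs: a 2×2 table with any zero margin has p = 1 by
  convention; zero mapped totals are errors for RPKM/CPM; an empty hit list
  resolves to `unmapped`; an empty transcript set is valid and generates
  nothing.
* Curation percentages round half away from zero at the stated precision
  (matching the printed 6.2%, 10.8% and 77% on their published
  numerator/denominator pairs).
* The GO functional-annotation clustering service upstream of the curation
  arithmetic is not re-implemented (external, version-dependent); its outputs
  enter as annotation tables. The packaged curation-chain fixture combines
  the published gene ids with clearly-labelled synthetic placeholder ids for
  the excluded genes whose identities are not fully public, preserving the
  published set sizes (68 merged − 18 − 12 = 38, + 15 manual = 53).
* The examined-gene fixture distinguishes `vascular_24hpf` (the published
  table's bold marks, 40 genes including the previously known positive
  control *she*) from `vascular_confirmed` (the 39 newly confirmed genes the
  text counts).

## Known limitations

* No indel or spliced alignment; transcript-space mapping only.
* No replicate-level variance modeling; the test is exact only under Poisson
  sampling and is anti-conservative on overdispersed real data.
* The read simulator's error model is substitution-only with uniform rate.
* Headline dataset-scale counts of the motivating study (e.g. its 849/726
  up/down-regulated entries from 123M reads) depend on unreleased raw data
  and are not reproduction targets; the package reproduces the method and the
  in-paper arithmetic, at desk scale.
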