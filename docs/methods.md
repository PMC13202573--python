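# Methods

This note documents the models, numerical choices and limitations of
`surfquant`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under which assumptions,
and what the bundled simulations do and do not demonstrate.

## The measurement model

A biotin/mock surfaceomics experiment produces, per LC-MS run, an MS1
feature map — centroids (retention time, m/z, intensity) — and a table
of MS/MS peptide identifications (sequence, charge, observed m/z, RT,
expectancy score, protein mapping). Quantification is MS1-only: the
identification tells us *where* a peptide ion lives in (m/z, RT) space;
the abundance is the area under its extracted ion chromatogram.

### XIC extraction and integration

* Window: ±7 ppm in m/z, ±1.5 min in RT (both inclusive, both
  configurable). Centroids sharing a scan time are summed.
* Reference coordinates for an ion come from its best-expectancy
  identification across runs; the same window is then applied to every
  sample (match-between-runs). No RT alignment is performed — the
  ±1.5 min window is assumed to absorb run-to-run drift. This is a
  documented limitation: gradients with drift approaching the window
  width would need external alignment.
* Peak detection: among local maxima of the trace, the apex nearest
  the identification RT wins. Boundaries extend outward to the first
  local minimum at or below 5 % of the apex intensity (or the trace
  ends). The 5 %-valley rule makes the integration deterministic and
  analytically checkable; the area is the trapezoid rule over the
  bounded segment. Empty and single-point traces are missing, not zero.
* Ions are accepted at expectancy < 0.05; duplicates of the same
  (peptide, charge) across runs collapse to a single quantified row.
  Charge states are **not** summed together: each (peptide, charge) is
  its own row, and the protein rollup sums whatever rows map to the
  protein. Whether the original should merge charge states is genuinely
  ambiguous; keeping them separate is the conservative choice and the
  rollup makes it immaterial for protein-level statistics.

### Rollup and normalization

Protein signal is the plain sum of non-missing peptide areas (missing
only if all peptides are missing). Proteins with fewer than two
distinct peptide sequences are dropped. Shared peptides count toward
every mapped protein for quantification, but differential results are
only *reported* for proteins with at least one unique peptide — the
`reportable` flag. Zeros are treated as missing; no pseudocounts.

Normalization: each sample's linear values are scaled by
median(sample totals)/(sample total), log2-transformed, and centred by
subtracting the per-sample median. Medians were chosen over means for
outlier robustness; the centring makes per-sample medians exactly zero.
Note that with a large fraction of truly enriched proteins this
composition-sensitive normalization shifts estimated fold changes
toward zero (as any total-signal normalization must); the noiseless
exactness checks therefore read raw fold change off the linear layer,
while the screening tests demonstrate that the shift leaves a true
Log2FC of 2 comfortably above the 0.5 gate.

## Differential screening

Two groups only (biotin vs mock); multi-cell-line studies run the
contrast per cell line. For each protein with at least two observations
per group: pooled variance s² on d = n₁+n₂−2 df, posterior variance
s²_post = (d₀s₀² + ds²)/(d₀+d), moderated t = Δ/√(s²_post(1/n₁+1/n₂)),
two-sided p from t with d+d₀ df.

Hyper-parameters (d₀, s₀²) are estimated by moment matching on
e = log s² − ψ(d/2) + log(d/2): the excess variance of e over its
sampling expectation ψ′(d/2) equals ψ′(d₀/2), solved by bisection on
the trigamma function to 1e-8; when the excess is non-positive d₀ is
reported as infinite (variances essentially constant; the posterior
variance is then s₀² for every protein and the reference distribution
is normal). This matches Bioconductor limma's `fitFDist`/`eBayes`
(non-robust, no trend) to ~1e-10 on shared inputs, which the test suite
verifies through Rscript as an independent oracle. Setting d₀ = 0
recovers the ordinary pooled t-test exactly.

Multiple testing: BH step-up across proteins (and, separately, across
ontology terms — never jointly). The default significance gate is
Log2FC > 0.5 with adjusted p < 0.1; both are configurable because
published analyses of this kind alternate between 0.1 and 0.25
depending on replicate structure.

Precision is reported as the per-protein CV (sd/mean on linear
quantities, n−1 denominator, percent) across replicates of the same
cell line and arm, summarised by the median.

## Enrichment

* ORA: hypergeometric upper tail P(X ≥ k) with the universe defined as
  the proteins actually quantified in the contrast (not the whole
  annotation) — enrichment is asked relative to what was measurable.
  Term membership is intersected with the universe before applying the
  3–350 size filter.
* GSEA: weighted-KS running sum (hit increments |stat|^w, w = 1,
  normalized within the set; uniform miss decrements), ES = largest
  deviation. The null permutes set membership (gene permutation),
  appropriate for small-replicate designs; NES divides by the mean
  |null ES| of matching sign and the empirical p carries +1 smoothing.
  Nulls are cached per set size. The default ranking metric is Log2FC.
  Ties in the ranking are broken by protein id, making results
  deterministic.
* Delta enrichment: the contrast of a term's annotated proportion
  between labelled (significant) and unlabelled proteins. The phrase
  "proportion of labelled relative to unlabelled" is ambiguous between
  a difference and a ratio; the difference of proportions is the
  default (antisymmetric, bounded) and the ratio is available by
  config.
* The surface:cytoplasm ratio divides hit counts in the two terms;
  a zero denominator is flagged (inf or NaN for 0/0) rather than
  raised.

## Absolute quantification

Signals are divided by the protein's **average** (not monoisotopic)
molecular weight computed from its FASTA sequence — calibration deals
in bulk molarity, where average masses are the correct convention.
Standard amounts convert as molecules = fmol × 1e−15 × 6.02214076e23.
The calibration line log10(signal/MW) = a·log10(molecules) + b is
ordinary least squares, fitted per experiment (standards are run
alongside the samples, so cross-experiment pooling would mix
instrument states). Copies per cell divide inverted molecule counts by
the number of labelled cells, default 1.2 × 10⁶; an injected-fraction
correction, if needed, can be folded into `n_cells`.

## The synthetic generator

The generator emulates the statistical structure of a biotin/mock
experiment, not mass spectra:

* Proteome: `n_proteins` split into surface (fraction 0.3 by default,
  true Log2FC = `enrichment_log2fc`, default 2), cytoplasmic leakage
  (0.2, true Log2FC +0.2 — deliberately below the 0.5 gate, modelling
  intracellular contamination that partially survives the screen), and
  bead binders (remainder, Log2FC 0). Base abundances are lognormal,
  10^N(6, 1) by default.
* Peptides: ~Poisson(10) per protein (minimum 2), random tryptic
  sequences (6–15 residues, K/R terminus, no internal K/R/P), one
  charge state (2 or 3) drawn from a stable sequence hash. Peptide
  ions are kept ≥ 25 ppm apart in m/z so that XICs are
  interference-free — real data contains near-isobaric interference
  the generator intentionally omits (chimeric signal is a non-goal).
* Chromatography: symmetric triangular peaks, 0.4 min base, sampled on
  a 0.05 min scan grid with apexes snapped to the grid; the sampled
  triangle then integrates *exactly* under the trapezoid rule, which is
  what makes the noiseless recovery contracts exact to float tolerance.
  Run-to-run RT jitter is N(0, 0.1 min).
* Noise: per peptide-sample multiplicative lognormal with unit mean
  and configurable CV (default 5 %, matching replicate precision in
  well-behaved label-free experiments). Missingness drops features at
  `missing_rate`, but each peptide survives in at least one run and is
  identified in at least one run (identification probability 0.7 per
  present run), exercising cross-run matching.
* Standards: 8 spike-ins log-uniform over 0.5–50 000 fmol (five
  decades, the dynamic range of commercial UPS2-style mixes), present
  identically in both arms, with signal = molecules × MW × 1e−3 so the
  log-log calibration slope is 1 by construction.
* Ontology: "cell surface" and "cytoplasm" terms matching the truth
  compartments, plus 10 random decoy terms.

Everything derives from a single seed; identical configs produce
byte-identical on-disk datasets.

**What passing tests show, and what they do not.** The simulations
validate the pipeline's arithmetic, its statistical calibration under
the stated noise law (lognormal noise is exactly normal on the log
scale, so type-I control there is a necessary but not sufficient check
for real data), and its recovery behaviour under clean, interference-
free chromatography. They do not exercise isotope envelopes, chimeric
peaks, RT warping, identification FDR, or intensity-dependent variance
— all absent from the generator by design.

## Problem sizes

The bundled checks use deliberately modest simulations chosen to pin
down the relevant behaviour: the calibration claim uses the standard
mix as specified (8 points × 3 draws, 100 repeat seeds for a stable
median); the precision claim uses 200 proteins × 8 samples through the
full XIC pipeline; screening calibration/power use 400 proteins (null)
and 100 proteins at 6+6 replicates (power). These sizes already give
Monte-Carlo errors well inside the asserted margins.

## Known limitations

* No RT alignment; the fixed RT window is the only defence against
  drift.
* One charge state per peptide in the generator; the quantifier
  handles multiple charge states but they are never merged before
  rollup.
* The eBayes prior has no intensity trend (limma-trend is out of
  scope) and assumes exchangeable variances.
* GSEA uses gene-permutation nulls only; phenotype permutation is out
  of scope.
* Absolute quantification requires spike-ins; proteome-ruler/iBAQ
  style estimates are out of scope.
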