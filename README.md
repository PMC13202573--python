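# surfquant

Quantitative analysis for biotinylation-based cell-surface proteomics
("surfaceomics"). Experiments of this kind label proteins on the surface
of living cells with biotin reagents, pull them down on streptavidin
beads, and measure the digested peptides by single-shot DDA LC-MS/MS. A
mock pull-down (vehicle instead of biotin) measures what sticks to the
beads nonspecifically; the science is in separating genuine surface
proteins from bead binders and cytoplasmic leakage, and in turning MS1
signal into interpretable quantities — relative fold changes, ontology
enrichment, and absolute copy numbers per cell.

`surfquant` implements that full pipeline as a tested Python library
with a thin CLI, plus a synthetic-data generator with known ground
truth so every stage can be validated without any raw MS download.

## What it computes

**Cross-run XIC label-free quantification.** For every peptide ion
identified (Mascot-style expectancy < 0.05) in *at least one* run, an
extracted ion chromatogram is built in every sample within ±7 ppm and
±1.5 min of the ion's reference coordinates (taken from its
best-scoring identification — match-between-runs). The peak whose apex
lies nearest the identification retention time is integrated by the
trapezoid rule between 5 %-of-apex valleys. Protein abundance is the
sum of its peptide areas; proteins need ≥ 2 distinct peptides, and
differential results are only reported for proteins with ≥ 1 unique
peptide. Normalization is median-of-totals scaling, log2, and
per-sample median centring.

**Empirical-Bayes differential screening.** For biotin vs mock, each
protein's pooled variance s² (d = n₁+n₂−2 df) is shrunk toward a prior
s₀² with d₀ prior df:

    s²_post = (d₀·s₀² + d·s²) / (d₀ + d),
    t = Δlog2 / sqrt(s²_post · (1/n₁ + 1/n₂)),   df = d + d₀,

with (d₀, s₀²) estimated by moment matching on the log residual
variances (trigamma inversion). P-values are BH-adjusted; the default
significance gate is Log2FC > 0.5 and adjusted p < 0.1. Replicate
precision is summarised as per-protein CVs (sd/mean, %).

**Ontology enrichment.** Hypergeometric over-representation (gene-set
sizes 3–350, BH across terms) and a weighted-KS GSEA with
set-membership permutation nulls, against user-supplied GMT files.
Also: the delta-enrichment statistic (difference of the annotated
proportion between labelled and unlabelled proteins), the
surface:cytoplasm hit-count ratio, and UpSet-style overlap summaries
between methods.

**Absolute copy numbers.** Protein signals are divided by the average
molecular weight computed from FASTA; spike-in standard amounts (fmol)
are converted to molecules with Avogadro's number; an OLS line of
log10(signal/MW) on log10(molecules) is fitted to the dynamic-range
standards, and inverting it converts any protein's signal into
molecules and copies per cell (default 1.2 × 10⁶ cells per reaction).

## Worked example

```python
import surfquant as sq

cfg = sq.SyntheticConfig(n_proteins=100, seed=42)   # 30 surface, 20 leakage, 50 bead binders
ds = sq.simulate_experiment(cfg)

pepmat, ion_meta = sq.quantify_across_runs(ds.identifications, ds.feature_maps, ds.design)
mw = dict(zip(ds.truth.proteins.accession, ds.truth.proteins.mw_da))
pqm = sq.normalize(sq.rollup_proteins(pepmat, ion_meta, mw))

res = sq.moderated_ttest(pqm, ds.design)
hits = sq.significant_proteins(res)
print(f"quantified proteins: {len(pqm.linear)}")
print(f"significant (Log2FC>0.5, adj-p<0.1): {len(hits)}")

readings = sq.simulate_standard_readings(seed=42)
curve = sq.fit_calibration(readings.signal / readings.mw_da, readings.molecules)
print(f"calibration: slope={curve.slope:.3f}, R^2={curve.r_squared:.4f}")
```

prints

```
quantified proteins: 108
significant (Log2FC>0.5, adj-p<0.1): 30
calibration: slope=1.009, R^2=0.9998
```

All 30 hits are the 30 true surface proteins (the generator applied a
Log2FC of 2 to them in the biotin arm); the 100 simulated proteins plus
8 spike-in standards give 108 quantified rows; and the spike-in
calibration comes back essentially linear on the log-log scale. The
biotin-replicate precision for this run is a median CV of 1.65 %, and
`sq.copies_per_cell` converts the biotin-arm means into copy numbers.

The same flow is available from the shell:

```sh
surfquant simulate --outdir ds --seed 42 --n-proteins 100
surfquant all --indir ds --outdir results
```

which writes peptide/protein matrices, contrast, ORA/GSEA tables,
calibration parameters, copy numbers and CV summaries as TSV, plus the
resolved configuration and a timestamped log.

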