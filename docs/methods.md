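# Methods

## The screening model

The pipeline analyses an arrayed RNAi screen in which each gene's knockdown
is measured as the mean DiI-LDL fluorescence of a well of cells, a proxy
for LDLR activity. Three structural assumptions drive every design choice:

1. **Plate effects are multiplicative.** Staining intensity, imaging gain
   and transfection efficiency scale whole plates up or down. Normalizing
   to the plate median and scaling by the plate MAD removes any per-plate
   affine transform of intensity; affine invariance of the z-scores is
   tested explicitly and is the formal content of "plate-effect removal".
2. **Outliers are the signal.** The wells we want to find are exactly the
   extreme ones, so the centre/scale estimates must be resistant to them —
   hence median/MAD rather than mean/SD. The MAD is left unscaled by
   default (consistency constant `c = 1.0`) so the hit threshold of 2 z
   units is literally "2 plate MADs"; `c = 1.4826` (Gaussian-consistent) is
   available in the config for analysts who want z on an SD-like scale.
3. **Cytotoxicity masquerades as signal.** A knockdown that kills cells
   produces a dim well regardless of LDLR biology. Wells with fewer than
   500 valid objects (segmented nuclei) are removed before any statistic is
   computed; the boundary is exclusive (499 fails, 500 passes).

Two readings of the normalization are possible: centre/scale from all wells
of the plate, or from the non-silencing control wells only. The default is
the plate-wide statistic (the NS wells are randomly distributed and included
in it); the NS-only variant is behind `scale_reference: ns_controls`. With
many hundreds of sample wells per plate, overwhelmingly null, the two differ
little; the switch exists because both conventions are common in screening
practice.

Median and MAD of even-sized samples use the mean-of-central-pair
convention, stated so that oracle tests can demand exact agreement.

## Decision rules and their parameters

| parameter | default | meaning |
|---|---|---|
| `min_valid_objects` | 500 cells | viability filter |
| `mad_consistency_constant` | 1.0 | MAD scaling (1.4826 = Gaussian SD) |
| `primary_z_threshold` | 2.0 | inclusive per-replicate hit bound |
| `primary_min_replicates` | 2 of 3 | concordant replicates required |
| `deconv_z_threshold` | 1.6 | inclusive per-siRNA validation bound |
| `deconv_min_sirnas` | 1 of 3 | siRNAs required, primary direction |
| `de_alpha` | 0.05 | raw two-sided t-test cutoff |
| `de_fc_threshold` | 1.1 | signed fold-change magnitude cutoff |

All thresholds are inclusive, matching the printed inequalities they encode.
Hit calls are directional: a gene whose replicates exceed the threshold in
contradictory directions is not a coherent phenotype and is called `none`
(with the 2-of-3 default this can only occur under nonstandard configs).
Deconvolution validation is conditional on the primary direction — an
individual siRNA scoring strongly in the *opposite* direction does not
validate the gene.

The expression test is a pooled-variance two-sample Student t on the linear
scale with df = n₁+n₂−2; duplicates per condition give df = 2 and the test
honours that exactly — no moderated or shrunken variance is used, which
would be a different method. With both groups at zero variance the p-value
degenerates: 1 for equal means, 0 (flagged) for unequal. A log2-scale test
variant exists in config; so does optional Benjamini–Hochberg adjustment,
off by default because the classification rule is defined on raw P ≤ 0.05.
A gene is "cholesterol-modulated" when statin (sterol depletion)
significantly raises it and/or native LDL (sterol loading) significantly
lowers it — the coherent SREBP2-target pattern; significant changes in the
wrong directions do not count. Candidate integration treats "and/or" as
inclusive OR of expression modulation and the lipid-GWAS flag; `and` and
`expression_only` policies are available for sensitivity analysis.

## The synthetic screen

The generator emulates the structure the analysis assumes, not the imaging
upstream of it. Well intensity is
`plate_factor x baseline x (1 + effect) x noise` with lognormal plate
factors (SD 0.15) and lognormal well noise scaled to unit mean at CV 0.15 —
intensities are positive and plate effects multiplicative, which is what
median normalization presumes. Cell counts are Poisson (mean 1500; 200 for
cytotoxic knockdowns and the KIF11 control, far below the 500-cell cutoff).
Controls per 384-well plate: 16 non-silencing, 4 NPC1 positive (+30%
uptake, the anchored effect of the assay's positive control), 4 LDLR
negative (−70%, a free parameter — the knockdown's published effect is
qualitative), 4 KIF11 cytotoxicity controls; positions are re-randomized on
every plate. Default spike-in rates are 2% up- and 2% down-regulators at
fractional effects 0.3–0.8 (≈3–8 plate MADs, since the relative plate MAD
at CV 0.15 is ≈0.10). Deconvolution siRNAs inherit the gene effect times an
efficacy drawn Uniform(0.3, 1.0) — pool deconvolution only makes sense if
individual siRNAs are heterogeneous. The expression experiment adds
Gaussian log2 noise (SD 0.1) to per-gene baselines, two replicates per
condition; 35% of genes are truly sterol-modulated (coherent statin-up /
nLDL-down shifts of 0.2–1.0 log2 units). GWAS flags are independent
Bernoulli(0.05) — only the intersection logic is in scope, the flag list
itself is an input.

What the generator does **not** model: spatial (row/column/edge) artifacts,
field-to-field imaging variation, siRNA off-target effects, correlated
noise between replicates, heavy-tailed single-well outliers beyond the
lognormal. Passing tests therefore demonstrate that the decision rules are
implemented exactly and calibrated under the assumed noise model — not that
the thresholds are optimal for any real screen.

## Calibration of the replicate rule

Under the null, the probability that a gene is called is
`P = Σ_{j≥k} C(r,j) u^j (1−u)^{r−j} + Σ_{j≥k} C(r,j) d^j (1−d)^{r−j}`,
where `u = P(z ≥ +t)` and `d = P(z ≤ −t)` for a single null well. The two
one-sided terms are kept separate for two reasons: the call is directional
(k concordant replicates), and lognormal noise is right-skewed, so `u > d`
in raw-MAD units. With `k > r/2` a gene cannot satisfy both directions and
the sum is exact. `u` and `d` have no convenient closed form under
median/MAD standardization on finite plates, so they are estimated by a
Monte-Carlo oracle that simulates complete plates (including the fixed-
effect positive/negative control wells) and tallies exceedances of the null
wells only — ≥10⁶ wells by default. At the defaults this predicts ≈4.1% of
null genes called, which the zero-effect screen reproduces within sampling
error; a naive two-sided version of the same binomial formula would predict
≈7.5% and is measurably wrong for the directional rule.

Recovery scoring is direction-aware (an up-call on a true down-regulator is
a false positive) and "true regulator" means exactly nonzero simulated
effect; an optional `min_effect` gray zone excludes weak spikes from both
TP and FN accounting. Unscorable genes (too many wells lost to viability
QC) leave the evaluation universe rather than counting as negatives.
The recall-vs-effect-size curve reuses one seed across effect sizes,
coupling the noise draws so monotonicity is not blurred by resampling.

## Problem sizes and numerics

The packaged calibration runs use 20,000 genes x 3 replicates for the null
screen, 10⁶ oracle wells, 2,000 genes with 100 spiked regulators for
recovery, and 5,000 genes for the expression-stage null — sizes at which
binomial standard errors are a few percent of the measured rates. Funnel
counts are validated for chain monotonicity (validated ≤ rescreened ≤
candidates ≤ hits ≤ scorable ≤ screened) at report construction; the
validation rate is stored at full precision and rounded only for display.
Ties in ranking are broken by gene identifier so output order is total and
reproducible. Every generator is deterministic given its seed; the CLI
writes a manifest (config snapshot, input digests, row counts) with each
stage so a run can be reproduced byte-for-byte.

## Known limitations

- No spatial plate correction (B-score, loess): deliberately out of scope,
  as the normalization being modelled uses none.
- The t-test at n = 2 per group has df = 2 and little power; the pipeline
  reproduces this faithfully rather than substituting a moderated test.
- The deconvolution validation rate of a synthetic run depends strongly on
  the efficacy distribution, which is a modeling choice surfaced in config,
  not an estimated quantity.
- Gene identifiers are opaque strings; no symbol/ID resolution is
  attempted.
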