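# Methods

## Study design and model

The pipeline analyses a matched three-grade design: each of `n_patients`
(default 9) contributes one osteophytic, one high-grade and one low-grade
cartilage sample, profiled on three molecular layers — methylation probes
(M-values), RNA (log2 expression) and protein (abundances).  All inference
is within-patient: for a contrast between two grades, each feature's
paired differences d_i = x_i,A − x_i,B are analysed as a one-sample
problem, which is exactly the least-squares fit with patient indicator
covariates restricted to those two grades (verified against an explicit
OLS fit in the test suite).  Patient-level intercepts therefore never bias
the effect estimates; they only vanish from the differences.

### Empirical-Bayes moderation

Per feature, logFC = mean(d), s² = var(d) with df = n − 1.  Variances are
assumed exchangeable with a scaled inverse-chi-square prior: s² ~ s₀²·F(df, d₀).
The hyperparameters are estimated by method of moments on
e = log s² − ψ(df/2) + log(df/2):

- var(e) − ψ′(df/2) = ψ′(d₀/2) gives d₀ via trigamma inversion (Newton
  iteration with a bracketing root-finder fallback, tolerance 1e-10);
- mean(e) gives s₀² once d₀ is known.

If the spread of log s² does not exceed what df alone explains, the
inverse problem has no finite solution and d₀ = ∞: all features share the
pooled variance and the statistic becomes z-like (normal reference).  This
is a documented branch, not an error; with homogeneous simulated noise it
is the common outcome.  Forcing d₀ = 0 recovers the ordinary paired t
(used as an oracle equivalence in tests; the full estimator was also
checked against an independent reference implementation during development
and agrees to machine precision).  Two-sided P-values throughout; 95% CIs
use the t quantile at d₀ + df.

BH adjustment is the standard step-up with running-minimum monotonisation
(delegated to `statsmodels.stats.multitest`); thresholding q ≤ α
reproduces the classical rejection set, which a property test asserts
against a direct enumeration.

### Thresholds

Two FDR levels matter downstream: a primary 0.001 (stringent headline
lists, probe-level DMR input, PCA feature selection) and a secondary 0.05
(supporting evidence in the other contrast, enrichment input lists).  The
pipeline validates primary ≤ secondary.

## DMR calling

A deliberately transparent re-specification of kernel-based region
callers: probes with q ≤ probe_fdr are sorted by position and merged into
maximal runs with inter-probe gaps ≤ lambda_bp (default 1000 bp, ≥ 2
probes), echoing the λ/C spirit of the established tools.  The region
statistic is a signed Stouffer combination, z_j = Φ⁻¹(1 − p_j/2)·sign(logFC_j),
region_p = 1 − Φ(|Σz|/√k), with BH across regions.  A region mixing
directions can partially self-cancel; because members are already
individually significant, mixed regions are rare.  Since the published
parameterisation of the original caller is unknown, region counts are not
expected to reproduce any particular study's count.

Coordinates are 1-based inclusive internally; BED export converts to the
0-based half-open dialect.  A region overlaps a gene iff the intervals
share ≥ 1 base; per-gene DMP summaries count the gene's own significant
probes inside overlapping regions, and `prop_pos_beta` is the fraction of
those with increased methylation in the first-named tissue.  A gene can
overlap a region while contributing zero annotated probes to it; its DMP
count is then 0.

## Cross-omics integration

Gene-ID mapping keeps only pairs where both the stable ID and the symbol
occur exactly once — dropping every ambiguous row on either side.

The triple-significant list intersects RNA-significant, protein-significant
and DMR-overlapped genes at the primary FDR.  Directional concordance is
defined on RNA vs protein logFC signs only; methylation direction
(hyper/hypo from `prop_pos_beta` ≥ 0.5) is reported but not part of the
concordance test, since methylation direction does not constrain
expression direction gene-by-gene.  Concordance is tested with the exact
one-sided binomial tail P(X ≥ k), X ~ Bin(n, ½), by summation — one-sided
because excess concordance is the alternative of interest.

Cross-contrast reports give the Spearman correlation of logFCs, the
same-sign fraction with its binomial P, and the fraction of features whose
95% CIs intersect between contrasts.  The PCA separation verdict first
searches exhaustively for a PC1 threshold that classifies the target grade
against the rest without error, then falls back to LDA on the PC1–PC2
scores; both are deterministic.

## Integrative enrichment

Per layer, enrichment of a set in the significant-gene list is the exact
one-sided hypergeometric tail over that layer's testable universe
(methylation universe = genes with probe annotation, significant genes =
DMR-overlapped genes; RNA/protein = the quantified features).  The three
P-values are combined with Fisher's statistic (reference χ² with 6 df,
used for ranking); the combination strategy is pluggable in principle, and
the final inference does not rest on it because significance comes from a
randomization null: per randomization, each layer's significant list is
re-drawn uniformly from its universe with the same size, all combined
statistics recomputed, and

    q(set) = [mean null count of sets with combined p ≤ p_set]
             / [observed count of sets with combined p ≤ p_set],

clipped to [0, 1] and monotonised from least to most significant.
Support filters then annotate each record: `single-layer-only` when
per-layer p < 0.05 on fewer than two layers, `insufficient-support` when
the overlap count N ≥ 5 on fewer than two layers ("genes contributing to
the enrichment" is read as the overlap count N).

n_rand ≥ 100 is enforced; 1000 is the default (null-count Monte-Carlo SE
at q ≈ 0.05 is then small relative to the decision threshold, and a
convergence test checks stability under doubling).

## The synthetic-data generator

The generator draws, per gene g:

- an affected flag (fraction 0.2 by default, drawn without replacement so
  the affected count is exact);
- a latent bivariate-normal pair (z_rna, z_prot) with correlation
  `rna_protein_corr` (default 0.6) whose **signs** couple the RNA and
  protein effect directions; magnitudes are independent draws
  `effect_scale_ovl · (1 + 0.5|N(0,1)|)` (default scale 1.5 log2 units),
  bounded away from zero so that "affected" genuinely means detectable at
  the study's sample size;
- a methylation direction independent of the expression direction (real
  data shows both hyper- and hypo-methylation among up- and down-regulated
  genes), applied to every probe of the gene with a per-probe attenuation
  in [0.7, 1] so the gene's probes shift coherently.

Measured values are baseline + patient intercept (SD 0.5) + grade effect +
Gaussian noise (SD 1.0 for RNA/protein on the log2 scale, 0.6 for
M-values).  Low grade is the reference; the osteophytic mean carries the
full effect δ.  Because the three grades share one mean per gene, the
three contrasts are additive (OvL = OvH + HvL), so the two attenuation
dials `effect_ratio_ovh` (default 0.9) and `effect_ratio_hvl` (default
0.3) cannot hold simultaneously as exact per-gene ratios; the generator
reconciles them by giving the high grade the mean
((1 − r_OvH) + r_HvL)/2 · δ (default 0.2·δ, hence realised ratios
OvH ≈ 0.8 and HvL ≈ 0.2).  This preserves the qualitative structure the
dials encode — osteophytic-vs-high differences nearly as large as
osteophytic-vs-low, high-vs-low strongly attenuated — which is what the
structure-reproduction checks assert.

Protein is generated for a random gene subset (default 660 of 2000,
mirroring the roughly one-third protein coverage of transcriptome-wide
studies) and shipped as raw abundances 2^signal so the published
normalisation path (sum-scaling, log2, quantile) is exercised end-to-end;
optional missingness (default off) feeds the complete-case filter.  Genes
are tiled on one synthetic chromosome (1 kb bodies, 2 kb gaps — gaps wider
than the merge window so regions stay gene-local), each gene receiving ≥ 2
probes at distinct uniform offsets.  Planted gene sets draw a configured
fraction of members from affected genes; decoy sets are uniform draws.

Default problem sizes are a deliberate scale-down (2000 genes, 660
proteins, 5 probes/gene vs the motivating study's 14 029 / 4 653 /
424 705): the statistical structure, not the feature count, is what the
validation targets, and full-scale sizes remain reachable through
`SimConfig`.  Monte-Carlo replicate counts in the tests and the acceptance
script (5–20 seeds per property) were likewise chosen as the smallest
sizes at which the binomial sampling error is small relative to the
asserted margins.

### What the generator does and does not emulate

It reproduces the paired design, effect attenuation across grades,
RNA–protein effect correlation, coherent probe-level methylation shifts
and planted enrichment.  It does **not** simulate count noise
(RNA enters as Gaussian log-expression), array chemistry or normalisation
artefacts, batch effects, missingness mechanisms beyond
missing-completely-at-random, within-patient correlation calibrated to
real tissue (the patient-effect SD is a free parameter), or realistic gene
length / probe density heterogeneity.  Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the assumed
generative model — not robustness to the full messiness of real
multi-omics data.

## Numerical choices

- P-value floors at 1e-300 before inverse-normal / log transforms.
- Quantile normalisation ties: tied input values receive the mean of the
  reference values at their rank positions, keeping ties tied and the
  transform idempotent.
- log2 of sum-normalised protein fractions uses no pseudo-count by
  default: after complete-case filtering of positive abundances all
  fractions are in (0, 1]; an optional epsilon exists for user data
  containing zeros.
- Beta values at exactly 0 or 1 are rejected; `clip_beta` (default
  eps 1e-6) is the explicit pre-step.
- Joint quantile normalisation across all samples (not within grade
  groups): one reference distribution for the whole matrix.
- Empirical-FDR ratios are clipped to [0, 1]; ties in observed combined
  P-values share the same observed count (right-continuous counting).
- All simulation randomness flows from a single `numpy` Generator per
  dataset; fixed seed gives byte-identical written output.

## Known limitations

- The region caller is a gap-merge re-specification, not a reimplementation
  of kernel-smoothed callers; absolute region counts are not comparable.
- With nine pairs, the moderated t's calibration relies on approximate
  normality of the paired differences; heavy-tailed real data would need
  robust variants not implemented here.
- The enrichment randomization permutes gene labels, not sample labels, so
  it conditions on the observed per-layer significant-list sizes and does
  not propagate uncertainty in the differential stage.
- RNA analysis assumes log-expression input; count-based precision weights
  are out of scope.
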