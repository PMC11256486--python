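# Methods notes

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Pipeline model

All quantification happens on the log2-ratio scale. Within each TMT
11-plex, ten experimental channels are referenced to one pooled-reference
channel, which makes ratios comparable across plexes because the pool is
the same physical mixture in every plex. The stage order is fixed:

1. **PSM filters.** Rank-1, accession-annotated PSMs with isolation
   interference ≤ the threshold (default 45 %, boundary retained). PSMs
   with *missing* interference are retained — absence of the QC value is
   not evidence of co-isolation. "Non-redundant" is read as rank 1 from
   the upstream 1 %-FDR search; search-engine FDR is not recomputed.
2. **Isotope impurity correction.** Observed reporter intensities satisfy
   `observed = M · true` with M the label-lot impurity matrix (rows =
   observed channel, columns = true channel). The system is solved exactly
   per PSM; missing channels are excluded by row/column deletion, negative
   components clamped to zero. The default M is the identity because lot
   certificates are input data, not constants of the method.
3. **Median scaling.** Within each plex, every channel is rescaled so all
   channel medians equal the plex grand median (idempotent). Scaling is
   within-plex — ratios are formed within plex anyway, and cross-plex
   level differences cancel in the reference ratio. A channel with no
   observed intensity is left unscaled with a warning.
4. **Reference ratios.** `log2(sample / reference)`; a zero or missing
   numerator or denominator yields a missing ratio (log of zero is
   undefined; zeros are treated as non-detections, never as tiny values).
5. **Peptide roll-up.** Median of PSM ratios per peptide sequence and
   sample, over observed values only; protein-group sets are unioned so
   shared peptides stay recognisable.
6. **Missingness filter.** A peptide is kept iff its missing fraction is
   ≤ 36 % within *every* recovery group. The stricter every-group reading
   of a per-group rule was chosen (configurable); the any-group reading
   admits peptides entirely absent in one group, which the imputation
   would then invent.
7. **Iterative-PCA imputation.** Mean-initialised, column-centred rank-k
   SVD refits until imputed cells move < tol (default k = 2, tol 1e-4,
   max 200 iterations, deterministic). k = 2 captures the two dominant
   structured axes of these data (group and residual batch) without
   over-fitting 30 columns. Observed cells are never altered; convergence
   failure warns and returns the last iterate.
8. **Quantile normalization.** Columns are mapped onto the mean of the
   column order statistics; ties get the mid-rank average. Applied after
   imputation on the complete matrix; idempotent.
9. **Batch correction.** Per feature, OLS on
   `[intercept | group | plex dummies, centre dummies]`; only the batch
   contribution is subtracted, so group-related variation is untouched.
   Batch correction uses the imputed values (the order filter → impute →
   normalize → correct is fixed; swapping normalization and correction
   changes outputs and is covered by a regression test).
10. **Unique-group filter and protein roll-up.** Peptides mapping to more
    than one protein group are removed; proteins are the symmetric trimmed
    mean of their peptides (default trim 0.20 per tail, count floored;
    plain mean below 3 peptides). The trim fraction is the main
    sensitivity knob of the roll-up: 0.20 discards one peptide per tail at
    5–9 peptides, which suppresses single-peptide outliers without
    surrendering efficiency.

## Differential abundance

Per feature, a fixed-effects linear model with treatment coding (reference
levels SR, paraplegia, Toledo, female, AIS A; age and storage time
mean-centred). Positive logFC = higher in NR. Covariates: injury level,
centre, **plex**, sex, age, storage time, plus AIS grade at protein level.

Plex is deliberately present both in the batch-correction stage and in the
model. Point-removal of plex effects consumes degrees of freedom that a
subsequent refit without plex does not account for; on null synthetic
studies this inflated the global-null any-rejection rate at BH 0.10 to
roughly 0.16. Keeping plex in the design restores the nominal rate
(≈ 0.08 over 80 null replicates) at a negligible cost in power — the same
reasoning by which centre appears in both stages. This is the package's
own calibration choice.

Variance moderation follows the standard empirical-Bayes construction: the
prior (d₀, s₀²) is estimated by moment matching on log s² (digamma mean
correction; trigamma inversion by Newton iteration for the excess
dispersion). Moment matching was preferred over likelihood maximisation
for determinism and testability. Degenerate cases: with no excess
dispersion in the observed log-variances the prior df is infinite and the
prior variance is the geometric mean of the s² (so identical residual
variances shrink to themselves and the moderated t equals the ordinary t);
`prior_df=0` disables moderation entirely. p-values use d₀ + d_g degrees
of freedom (normal when d₀ = ∞), BH-adjusted.

Thresholds adapt to the data: `log2(FCT) = 1.47 × median per-feature SD`
across all samples; defaults α = 0.01 / FCT 1.8 for peptides,
α = 0.05 / FCT 1.6 / FDR ≤ 0.1 for proteins. Fold enrichments are
`2^|logFC|` rounded half-even to two decimals.

## FDR-controlled power

The per-comparison level α_c solves
`π₀ α_c / ((1−π₀) P(α_c)) = f/(1−f)` with `P(α)` the two-sided power of the
noncentral t (df = 2(n−1), ncp = Δ/(σ√(2/n))), found by bisection on
(1e-12, 0.5) to 1e-10. The fixed point equates the expected false/true
discovery mix to the target FDR *f*, i.e. it controls E(V)/E(R) = f.
Noncentral-t power (not a normal approximation) is required to reproduce
0.91 (n = 10) and 0.81 (n = 8) at the study parameters. Equal group sizes
are assumed — the study evaluated n at the size of its smallest group
despite 20 vs 10. Numerical guards: extreme tail quantiles where the
noncentral-t CDF fails evaluate as NaN and the bracket steps past them;
when the constraint never binds (π₀ → 0) α_c is reported at the bracket
cap, matching the limit of an unconstrained test; a genuinely infeasible
spec reports power 0 with a warning.

The independent simulation oracle for this computation applies
**π₀-calibrated BH** (level f/π₀) to 50,000 simulated t-tests: plain BH
controls FDR at π₀·f, not f, so it sits systematically below the fixed
point; the adaptive variant controls the same functional and agrees within
0.7 percentage points across the tested grid (realized false-discovery
proportions ≈ f confirm the functional).

π₀ estimation mirrors the qvalue smoother: π₀(λ) on the grid
0.05…0.95, a 3-df natural cubic regression spline (knots at the grid
quantiles), evaluated at λ = 0.95 and clipped to (0, 1]. The basis is
hand-built (small closed form) rather than pulled from a formula package.

## Enrichment

Two-sided Fisher exact test (minimum-likelihood convention: sum of all
tables with probability ≤ the observed one) per term, on
{regulated, non-regulated} × {in term, not}; the background is the
non-regulated feature set, disjoint from the regulated set by
construction. Peptides map to identifiers via their protein group before
matching; terms with fewer than 2 regulated matches are not tested and BH
runs over tested terms only. Terms are flat sets — no GO-graph ancestor
propagation. Depletion is reported via a direction field.

## ELISA

5PL parameterisation `OD = d + (a−d)/(1+(x/c)^b)^g` with a the
zero-concentration (lower) asymptote; fitted by least squares against the
simple linear model, higher r² wins, 5PL non-convergence falls back to
linear with a warning; r² ≤ 0.99 is flagged against the acceptance rule.
Interpolation inverts the selected curve and multiplies by the dilution
factor; ODs outside the asymptotes are non-invertible, concentrations
outside the standard range are flagged. LoB/LoD use the CLSI-style
formulas on the OD scale (the formulas as printed operate on measured
response; mapping through the curve is available afterwards). Both limits
are shift-equivariant. The normality gate runs Shapiro-Wilk per group at
α = 0.05; either group rejecting (or being constant, where normality
cannot be assessed) routes to a two-sided Mann-Whitney test, exact for
small tie-free samples; otherwise Student's t. No multiplicity adjustment
is applied across pairwise group comparisons. Four-group designs are
handled as repeated two-group calls.

## Synthetic-data generator

The generator emulates: the cohort layout (20 NR / 10 SR over three
11-plexes, one pooled-reference channel per plex declared in metadata);
additive log2 structure (protein baseline ~ N(14, 1.5²); group effect
± 0.68/2 on an `frac_affected` subset; per-protein plex and centre
offsets ~ N(0, 0.2²) and N(0, 0.1²); per-protein biological SD from a
scaled inverse-chi-square with d₀ = 6); peptide ionisation offsets and
peptide/PSM measurement noise; a reference pool mixed on the raw scale
from all samples; MNAR missingness
`p = mcar + (1−mcar)·logistic(slope·(threshold − latent))` over an MCAR
floor; shared peptides, unannotated and redundant PSMs, and a beta-shaped
isolation-interference distribution.

Calibrated defaults, chosen once: `frac_affected = 0.34` so the null
fraction matches the study's π₀ = 0.66; the biological-SD scale is
0.94 × the 0.4375 target so that the *final* protein matrix — after
roll-ups, normalization and batch correction add and remove variance —
lands near a median per-protein SD of 0.4375 (verified within 15 % as a
test); plex effects are applied to experimental channels only, since a
uniform plex shift would cancel in the reference ratio and leave nothing
for batch correction to find; centres alternate within each recovery group
so batch is crossed with, not aliased to, the contrast. Peptides-per-
protein (1–20) and PSMs-per-peptide (1–5) ranges are conventional choices,
not derivable from the study, and are configurable.

Not emulated: chromatographic fractions, charge states, spectral noise,
protein-grouping parsimony (groups are planted), or real annotation
catalogues (terms are planted sets). Consequently, passing tests show the
*procedures* behave correctly under the assumed additive/MNAR model — they
do not certify performance on real serum data, where peptide-level
interference and non-additive batch structure can be worse.

Test and acceptance runs use a scaled-down study (120–300 proteins,
shorter peptide lists) with the cohort's full sample layout; these sizes
are stated in the fixtures and keep a pipeline run below a second while
leaving every per-protein quantity at its cohort-scale operating point
(same n = 30, same SD target, same thresholds).

## Known limitations

- The moderated model treats samples as exchangeable given covariates;
  shared reference-pool noise induces a small within-plex correlation the
  model does not represent (mitigated by plex in the design).
- Imputed values enter batch correction and the models as if observed,
  slightly understating uncertainty for high-missingness peptides — the
  cost of the fixed impute-then-model order.
- π₀ spline estimation differs from a smoothing spline by the choice of
  regression knots; differences are well inside the estimator's own
  variance.
- The ELISA module reproduces procedures (calibration, limits, QC,
  testing); cohort concentration tables require the original sera.
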