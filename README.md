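# tmtserum

Analysis pipeline for **TMT 11-plex serum proteomics** of neurological
recovery after spinal cord injury: from peptide-spectrum-match (PSM) tables
to covariate-adjusted moderated differential abundance, FDR-controlled power
analysis, peptide-level functional enrichment, and ELISA validation
statistics.

The scientific setting: serum depleted of high-abundance proteins is
quantified by isobaric tandem-mass-tag reporter ions (channels 126–131C,
ten patient samples plus one pooled reference per plex) to find
low-abundance proteins whose levels differ between patients with **no
recovery (NR)** and **strong recovery (SR)** in the subacute phase of spinal
cord injury. Raw patient data are not publicly deposited, so the package
ships a first-class synthetic-study generator that emulates the cohort
design (30 patients over three 11-plexes, plex and centre batch effects,
intensity-dependent missingness, planted log2 group effects) and every
stage is tested against that ground truth.

## The methods at the core

**Data assembly** — PSMs are filtered (rank-1, annotated, isolation
interference ≤ 45 %), isotope-impurity corrected (solve *M x = observed*
per PSM), median-scaled per channel within each plex, expressed as
log2 ratios to the plex reference pool, and rolled up to peptides by the
median; peptides with > 36 % missingness in either group are dropped, the
rest imputed by iterative PCA, quantile normalized, batch-corrected for
plex and centre with the group contrast protected, restricted to unique
protein groups and rolled up to proteins by a 20 % trimmed mean.

**Moderated differential abundance** — per feature *g* a linear model with
covariates (injury level, centre, plex, sex, age, storage time, and at
protein level AIS grade) yields logFC β̂_g and residual variance s²_g; an
empirical-Bayes prior (d₀, s₀²) estimated by trigamma moment matching
shrinks variances,

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),   t_g = β̂_g / (u_g s̃_g),

with p-values on d₀ + d_g degrees of freedom and Benjamini–Hochberg
adjustment. Significance uses a **variance-adaptive fold-change threshold**

    log2(FCT) = 1.47 × median SD,

giving FCT = 1.6 at the protein level (median SD 0.4375) and 1.8 at the
peptide level.

**FDR-controlled power** — solve for the per-comparison level α_c with

    π₀ α_c / ((1 − π₀) P(α_c)) = f / (1 − f),

where P(α) is two-sided noncentral-t power with df = 2(n−1) and
ncp = Δ/(σ√(2/n)); π₀ is estimated qvalue-style (spline through
π₀(λ) = #{p > λ}/(m(1−λ))).

**Enrichment and ELISA** — two-sided Fisher exact over-representation of
annotation terms among regulated peptides against the non-regulated
background (min 2 matches, BH-adjusted p < 0.3); ELISA plates are reduced
with 5PL or linear standard curves chosen by r², LoB = mean_blank +
1.645·SD_blank, LoD = LoB + 1.645·SD_lowest-standard, duplicate CV QC, and
Shapiro-gated t / Mann-Whitney group comparisons.

## Worked example

```sh
python examples/power_analysis.py
```

prints (excerpt)

```
n per group   alpha_c      power
         8   0.04660   0.8142
        10   0.05214   0.9109  <- smallest group of the cohort
smallest n with power >= 0.8: 8
```

i.e. with effect size 0.68, SD 0.4375, π₀ = 0.66 and FDR 0.1, ten patients
per group give average power 0.91, and eight would already suffice for the
conventional 0.8. `examples/run_full_pipeline.py` runs the whole chain on a
synthetic cohort and prints the stage report (7 assembly + 5 preprocessing
stages), the adaptive thresholds, significance class counts, the mean
recovered effect on truly affected proteins (≈ 0.63 vs 0.68 planted at
default noise) and the planted-term enrichment table;
`examples/elisa_calibration.py` and `examples/fold_change_thresholds.py`
cover the validation statistics and threshold arithmetic.

A thin CLI mirrors the stages:

```sh
tmtserum simulate --out-dir sim --seed 3
tmtserum run-all --psm sim/psm.tsv --meta sim/metadata.tsv \
         --gmt sim/annotations.gmt --out-dir results
tmtserum power --n 10
```

## Layout

- `src/tmtserum/` — `datamodel` (types, TSV I/O, config), `assembly`,
  `preprocess`, `diffexp`, `power`, `enrichment`, `elisa`, `synthetic`,
  `pipeline`, `cli`
- `tests/` — unit, property and acceptance tests (all synthetic, no
  downloads)
- `docs/methods.md` — model assumptions, parameter choices, limitations
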