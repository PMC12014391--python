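# Methods

This note records the models implemented by `adhesiometry`, the
assumptions behind their defaults, the numerical choices that matter, and
the known limits of what the synthetic-data tests demonstrate.

## Chamber model

The divergent parallel-plate chamber is modelled analytically: width
`w(L) = w_min · exp(ln(10) · L / L_max)` and wall shear
`τ(L) = 6Qμ / (w h²)` for fully developed laminar flow between parallel
plates.  The exact 10-fold widening over the divergent length is adopted
as the design intent of the device; entrance effects, the V-shaped outlet
beyond `L_max` (where shear decays to zero) and any finite-element
corrections are out of scope, and analysis is restricted to the imaged
region.

Defaults (all overridable through the config schema):

| parameter | default | basis |
|---|---|---|
| `w_min` | 2.1 mm | throat width; assumption consistent with the 2.1 mm scan width |
| `h` | 127 μm | gasket thickness (reading the published "127 mm" as a μm typo) |
| imaged region | 61 × 775 μm = 47.275 mm | bin-derived length; the alternative printed value (45 mm) is not used |
| `L_max` | = imaged region | scan assumed to start at the throat |
| `n_bins` | 61 | equal-length bins, half-open `[start, end)`, last bin closed |
| μ | 0.01 poise | aqueous buffer at room temperature |
| τ_max | 660 dyn/cm² | the standard high-shear perfusion setting |

Positions are measured in cm from the throat toward the wide end;
internal computation is CGS throughout, with μm/μL converters only at
the I/O boundary.

## One-population Weibull fits

Per-bin survival `S = n_post/n_pre` (clamped to [0, 1]; bins that gained
cells are clamped and counted, bins with no pre-shear cells are excluded)
is fit by **unweighted** nonlinear least squares to
`S(τ) = exp(−(τ/λ)^k)`.  Unweighted residuals on the binned fractions
match standard curve-fitting-toolbox practice for this assay; weighting
by √n_pre is available but off by default.  Initialization: λ₀ from the
linearly interpolated shear at which empirical S crosses 0.5 (fallback:
median bin shear), k₀ = 2; bounds λ ∈ (0, 10·max τ], k ∈ (0, 20].  A fit
is flagged failed when the optimizer does not converge, a parameter ends
on its bound, or R² < 0; constant-survival profiles raise instead of
returning a meaningless optimum.

τ50 and τ75 are the closed-form quantiles `λ(−ln f)^(1/k)` at survival
f = 0.5 and 0.75 (τ75 is the shear at which a quarter of cells have
detached; it is always below τ50).  Technical replicates pass QC when
R² > 0.5; survivors are averaged per bin (simple mean, SEM recorded) and
the average refit.

Confidence and prediction bands use the Gauss–Newton covariance
`s²(JᵀJ)⁻¹` propagated to first order (delta method) through the model,
with Student-t critical values on n−2 degrees of freedom; the prediction
band adds the residual variance, and the τ75 interval applies the delta
method to the quantile formula.  Under the band's own error model
(homoscedastic Gaussian bin noise) the 95% τ75 interval covers the truth
in ≈95% of replicate simulations.  **Limitation:** real bin fractions are
binomial and heteroscedastic; at ~65 cells per bin the homoscedastic
covariance undercovers (≈82% observed), a property shared by any
toolbox-style least-squares interval on this data type.

## Two-population deconvolution

With the host (reference) Weibull fixed, the mixed profile is fit to
`S(τ) = Pc·exp(−(τ/λ)^k) + (1−Pc)·exp(−(τ/λ_ref)^k_ref)` by bounded
least squares over (Pc, λ, k).  The objective is multimodal when the
cancer component is faint (small Pc) or lies close to the host, so the
fit is globalized deterministically:

- multi-start over Pc₀ ∈ {0.25, 0.5, 0.75}, each with the free component
  initialized by *host subtraction* — fitting a one-population Weibull to
  `(S − (1−Pc₀)·S_host)/Pc₀` clipped to [0, 1];
- the one-population fit of the whole profile as an additional start per
  Pc₀;
- a coarse vectorized SSE scan over Pc × τ50 × k (20 × 30 × 5 points)
  whose best three cells seed further refinements.

Lowest SSE wins; exact ties break toward larger Pc.  The free component
is by convention the weakly adherent one; a fit whose free τ50 exceeds
the host's is flagged `label_ambiguous`.  A fit is flagged
`identifiability_warning` when an F-test of the 3-parameter mixture
against the fully fixed pure-host model is non-significant (p > 0.05) —
host-only data leave Pc on a flat ridge, and the flag, not a small Pc,
is the reliable signal — or when the fitted free component is
near-identical to the host.  Host-fit uncertainty is treated as a point
estimate and not propagated.

### Recovery study

The validation experiment draws, for each grid point of true
(τ50 ∈ [50, 150] dyn/cm², k ∈ [1.5, 3], Pc ∈ [0.1, 0.9]; the grid is
factored as evenly as possible, e.g. 8×6×4 = 192), a slide of 4,000
cells, runs the virtual chamber experiment, bins, deconvolves, and
records absolute τ50 and Pc errors (fit failures count as outside
tolerance).  At this scale the recovery rate is ≈0.80 within
±20 dyn/cm² for τ50 and ≈0.82 within ±0.06 for Pc (means over 10 seeds;
single-run SD ≈ 0.03 — a 192-draw binomial statistic).  Errors
concentrate at faint mixtures (Pc ≈ 0.1) and at cancer components
approaching the host, where a "compromise" single-population solution
can genuinely attain the global least-squares optimum for some noise
draws: this is an identifiability property of the model at this cell
count, not an optimizer artifact (audited by comparing every failed fit
against a truth-started refinement).  The known-ratio co-culture
simulation (25:75, 50:50, 75:25; ≥3 replicates at 4,000 cells) recovers
all fractions within a few percentage points and τ50 well inside
±43 dyn/cm².

## Risk layer

High risk is a nodule count ≥ 2 (the threshold can be re-derived by
scanning candidates for the minimum two-sided Wilcoxon rank-sum p
between groups; the test is exact for combined n ≤ 20 without ties —
mouse-cohort scale — and a tie-corrected normal approximation
otherwise, with ties in the scan broken toward the smaller threshold).
The classifier `logit(p) = a + b·τ50 + c·Pc + d·τ50·Pc` is fit by
maximum likelihood (IRLS via statsmodels GLM/Binomial, tolerance 1e-10,
≤100 iterations) on natural predictor scales; replicate rows are
averaged per sample by default.  Complete separation is flagged, not
fatal.  The deviance test refers `deviance(constant) − deviance(full)`
to χ² with 3 degrees of freedom.  ROC curves sweep every distinct score
threshold; trapezoidal AUC equals the pairwise concordance probability
with ties counted ½ (property-tested against a brute-force oracle and
scikit-learn).  The reported operating point maximizes Youden's J, with
the full sensitivity/specificity table always emitted so any other
operating rule can be read off.

## Synthetic data

The generator is the package's virtual instrument.  Detachment is a
threshold process: a cell detaches iff its drawn adhesion strength is
below the local wall shear at its (uniformly seeded) position, so
expected bin survival equals the population survival at bin-center
shear.  Strengths are inverse-CDF Weibull draws; mixed slides label each
cell cancer with probability Pc.  Default populations — cancer τ50 = 90
dyn/cm² (k = 2), host τ50 = 300 dyn/cm² (k = 3) — respect the published
constraints (metastatic lines detach below ~150 dyn/cm²; host roughly
3-fold stronger) but are otherwise this package's assumptions, as the
underlying line-specific parameters are not public.  Default scale is
4,000 analyzed cells per slide, with an 80,000-cell high-density preset.

Cohorts draw per-animal true (τ50, k, Pc) uniformly over the metastatic
ranges and nodule counts from a Poisson log-linear link,
`log E[nodules] = 0.7 − 0.015·(τ50−100) + 3.0·(Pc−0.3)`, giving
realistic 0–15 counts centred near the risk threshold; biomarkers are
then measured either exactly or through the full virtual assay.  The
link is a modelling assumption confined to this module.  Randomness uses
one stream per (seed, operation) so adding a stage never shifts
another's draws; identical spec + seed reproduces outputs byte for byte.

**What passing tests do not show:** the generator has no cell migration
between bins during shearing, no stochastic detachment kinetics, no
cell-cycle or ligand-density effects, and cohort biomarker–outcome
coupling is exactly log-linear; agreement of the pipeline with this
generator validates the inference machinery, not the biology of any real
cohort.

## Problem sizes

Simulation-backed tests run at the study's own scales — 192/196-mixture
recovery grids at 4,000 cells, 500-replicate coverage checks, 100
synthetic cohorts of n = 500 for coefficient recovery, 50 cohorts of 40
animals for the model-comparison experiment — chosen to keep Monte-Carlo
error small relative to each asserted margin.
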