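# adhesiometry

Label-free adhesion-mechanotype analysis for divergent parallel-plate
flow-chamber (dPPFC) assays.

Weakly adherent tumor cells are the ones that escape a primary tumor,
migrate through stroma and seed metastases.  A dPPFC measures adhesion
strength without labels: the channel widens exponentially along its
length, so a single perfusion exposes cells seeded along the chamber to a
continuously decreasing wall shear stress, and imaging nuclei before and
after flow yields the fraction of cells remaining as a function of shear
— the *adhesion profile*.  This package implements the downstream
computational pipeline for such assays: the position→shear map, Weibull
survival fits, two-population deconvolution of mixed samples, a
simulation-based validation of that deconvolution, and a logistic /
ROC metastatic-risk layer.  It is aimed at quantitative cell biologists
and biostatisticians working with detachment assays.

## Models

**Chamber.** Side walls diverge as `w(L) = w_min · exp(ln(10) · L / L_max)`
(a 10-fold widening), so the wall shear stress under laminar flow,

    τ(L) = 6 Q μ / (w(L) h²),

decreases exponentially from its maximum at the throat.  The imaged
region is tiled by equal-length bins (default 61 × 775 μm) and each bin
reports the shear at its center.  All computation is CGS (cm, s, poise,
dyn/cm²).

**Adhesion profile.** Per-bin survival `S = n_post / n_pre` is fit to a
Weibull survival model

    S(τ) = exp(−(τ/λ)^k),

with scale λ (dyn/cm²) and shape k.  Adhesion strength is summarized by
the quantiles τ50 = λ(ln 2)^(1/k) (half the cells detached) and
τ75 = λ(−ln 0.75)^(1/k) (a quarter detached, used for heterogeneous
primary tissue).  Replicates with R² > 0.5 are averaged; 95% confidence
and prediction bands come from delta-method propagation of the fit
covariance.

**Deconvolution.** A biopsy mixes a weakly adherent cancer population
with a strongly adherent host population.  With host parameters
(λ_ref, k_ref) measured separately (e.g. from a contralateral fat pad)
and held fixed, the mixed profile is fit to

    S(τ) = Pc · exp(−(τ/λ)^k) + (1 − Pc) · exp(−(τ/λ_ref)^k_ref),

recovering the cancer fraction Pc and the cancer component's τ50.  A
Monte-Carlo recovery study quantifies accuracy at experimental scale
(~4,000 cells/slide over a grid of true τ50, k, Pc).

**Risk.** Each animal contributes (τ50, Pc) and a lung-nodule count;
high risk means ≥ 2 nodules (the threshold can be re-derived by a
Wilcoxon rank-sum scan).  The classifier is the logistic model
`logit(p) = a + b·τ50 + c·Pc + d·τ50·Pc`, tested against the constant
model by a deviance (likelihood-ratio) test and scored by ROC/AUC with
the fitted probabilities as scores.

## Worked example

Simulate a 50:50 co-culture of a weakly adherent (τ50 = 90 dyn/cm²,
k = 2) and a strongly adherent reference population (τ50 = 300 dyn/cm²,
k = 3) at experimental scale, then deconvolve it:

```python
from adhesiometry import (
    DEFAULT_CANCER, DEFAULT_HOST, default_geometry, build_profile,
    fit_mixture, simulate_experiment,
)
from adhesiometry.synthetic import default_flow

geometry = default_geometry()          # 61 bins x 775 um, h = 127 um
flow = default_flow(geometry)          # 660 dyn/cm^2 at the throat

pre, post = simulate_experiment(
    cancer=DEFAULT_CANCER, host=DEFAULT_HOST, Pc=0.50, n_cells=4000,
    geometry=geometry, flow=flow, rng=42,
)
profile = build_profile(pre, post, geometry, flow)
fit = fit_mixture(profile, DEFAULT_HOST)
print(f"cancer fraction Pc = {fit.Pc:.3f}   (true 0.500)")
print(f"cancer tau50       = {fit.tau50_cancer:.1f} dyn/cm^2  (true 90.0)")
print(f"goodness of fit    = R^2 {fit.r_squared:.4f}")
```

prints

```
cancer fraction Pc = 0.502   (true 0.500)
cancer tau50       = 84.8 dyn/cm^2  (true 90.0)
goodness of fit    = R^2 0.9802
```

i.e. the mixture fit recovers the seeded cancer fraction to half a
percentage point and the cancer component's median detachment shear to
about 5 dyn/cm² on this slide.  The same steps are available from the
shell (`adhesiometry simulate`, `profile`, `fit`, `deconvolve`, `risk`,
`roc`, `run`; see `adhesiometry --help`).

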