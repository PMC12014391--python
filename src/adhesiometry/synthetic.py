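"""Synthetic data generation for the adhesion-profiling pipeline.

Everything the analysis consumes can be generated here under explicit
seeds: single-cell detachment thresholds drawn from Weibull distributions,
virtual chamber experiments at experimental seeding scale (~4,000 analyzed
cells per slide), known-ratio co-cultures, technical replicates, and mouse
cohorts in which lung-nodule counts rise with the cancer fraction and fall
with adhesion strength.

Detachment is modelled as a threshold process: a cell whose adhesion
strength is below the local wall shear detaches, so the expected per-bin
survival equals the population survival function evaluated at the bin
shear.  Stochastic detachment kinetics are deliberately not modelled.

The default populations are synthetic stand-ins for a weakly adherent
metastatic line and a strongly adherent host/epithelial population; their
parameters are chosen to respect the published constraints (metastatic
lines detach below ~150 dyn/cm^2; host cells roughly 3-fold stronger) but
are otherwise assumptions of this package.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chamber import (
    ChamberGeometry,
    FlowCondition,
    bin_boundaries,
    default_geometry,
    shear_at_position,
)
from .profiles import CellObservationSet, WeibullParams

__all__ = [
    "SyntheticSpec",
    "weibull_from_tau50",
    "DEFAULT_HOST",
    "DEFAULT_CANCER",
    "sample_population",
    "simulate_experiment",
    "simulate_cohort",
    "default_flow",
]

#: Cells analyzed per slide in a standard run (~4,000 over the imaged region).
DEFAULT_N_CELLS = 4000
#: Cells per slide in the high-density preset (8 x 10^4 seeded per slide).
HIGH_DENSITY_N_CELLS = 80_000


def weibull_from_tau50(tau50: float, k: float) -> WeibullParams:
    """Weibull parameters with the requested median detachment shear.

    Inverts tau50 = lam * (ln 2)**(1/k).
    """
    if tau50 <= 0 or k <= 0:
        raise ValueError("tau50 and k must be positive")
    lam = tau50 / (math.log(2.0)) ** (1.0 / k)
    return WeibullParams(lam=lam, k=k)


#: Strongly adherent reference population (host / non-metastatic):
#: tau50 = 300 dyn/cm^2, shape 3 — about 3-fold stronger than the
#: metastatic default below.
DEFAULT_HOST = weibull_from_tau50(300.0, 3.0)

#: Weakly adherent metastatic population: tau50 = 90 dyn/cm^2, shape 2.
DEFAULT_CANCER = weibull_from_tau50(90.0, 2.0)


def default_flow(
    geometry: ChamberGeometry | None = None,
    tau_max: float = 660.0,
    mu: float = 0.01,
) -> FlowCondition:
    """Perfusion producing the standard maximum shear (660 dyn/cm^2 at the
    throat) with an aqueous buffer (mu = 0.01 poise)."""
    geometry = geometry or default_geometry()
    return FlowCondition.from_max_shear(geometry, mu=mu, tau_max=tau_max)


def _op_rng(seed: int, operation: str) -> np.random.Generator:
    """Independent stream per (seed, operation name).

    Keying streams by operation keeps draws for one stage stable when
    another stage is added or reordered.
    """
    key = zlib.crc32(operation.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_population(
    params: WeibullParams, n: int, rng=0
) -> np.ndarray:
    """Draw ``n`` single-cell adhesion strengths (dyn/cm^2).

    Inverse-CDF sampling: tau_i = lam * (-ln U_i)**(1/k) with U_i uniform
    on (0, 1); reproducible given a seed or Generator.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    g = _as_rng(rng)
    u = g.uniform(0.0, 1.0, size=n)
    # guard the measure-zero endpoints so log stays finite
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return params.lam * (-np.log(u)) ** (1.0 / params.k)


def simulate_experiment(
    cancer: WeibullParams | None,
    host: WeibullParams | None,
    Pc: float,
    n_cells: int,
    geometry: ChamberGeometry,
    flow: FlowCondition,
    rng=0,
    slide_id: str = "sim",
    replicate_id: str = "r0",
) -> tuple[CellObservationSet, CellObservationSet]:
    """Virtual chamber run on a (possibly mixed) population.

    Cells are seeded uniformly over the imaged region; each is labelled
    cancer with probability ``Pc`` and assigned a strength drawn from its
    population's Weibull distribution; after perfusion exactly the cells
    whose strength is at least the local wall shear remain.  Returns the
    (pre, post) observation sets ready for profile building.
    """
    if not 0.0 <= Pc <= 1.0:
        raise ValueError(f"Pc must lie in [0, 1], got {Pc}")
    if Pc > 0 and cancer is None:
        raise ValueError("cancer population required when Pc > 0")
    if Pc < 1 and host is None:
        raise ValueError("host population required when Pc < 1")
    g = _as_rng(rng)
    edges = bin_boundaries(geometry)
    positions = g.uniform(edges[0], edges[-1], size=n_cells)
    is_cancer = g.uniform(size=n_cells) < Pc
    strengths = np.empty(n_cells)
    n_c = int(is_cancer.sum())
    if n_c:
        strengths[is_cancer] = sample_population(cancer, n_c, g)
    if n_cells - n_c:
        strengths[~is_cancer] = sample_population(host, n_cells - n_c, g)
    local_shear = shear_at_position(geometry, flow, positions)
    remains = strengths >= local_shear
    pre = CellObservationSet(slide_id, replicate_id, "pre", positions)
    post = CellObservationSet(slide_id, replicate_id, "post", positions[remains])
    return pre, post


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a full synthetic study.

    Cohort link: per animal, the expected lung-nodule count follows a
    log-linear Poisson model,

        log E[nodules] = baseline_log_nodules
                         + coef_tau50 * (tau50 - 100)
                         + coef_pc    * (Pc - 0.3)

    centred so the baseline is the expected log-count for a mid-range
    animal (tau50 = 100 dyn/cm^2, Pc = 0.3).  Nodule counts therefore rise
    with the cancer fraction and fall with adhesion strength; the link is
    a modelling assumption of this generator, not a measured law.
    """

    cancer: WeibullParams = DEFAULT_CANCER
    host: WeibullParams = DEFAULT_HOST
    Pc: float = 0.5
    n_cells: int = DEFAULT_N_CELLS
    n_samples: int = 18
    seed: int = 0
    tau50_range: tuple[float, float] = (50.0, 150.0)
    k_range: tuple[float, float] = (1.5, 3.0)
    pc_range: tuple[float, float] = (0.05, 0.6)
    baseline_log_nodules: float = 0.7
    coef_tau50: float = -0.015
    coef_pc: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.Pc <= 1.0:
            raise ValueError("Pc must lie in [0, 1]")
        if self.n_cells < 1 or self.n_samples < 1:
            raise ValueError("n_cells and n_samples must be >= 1")


def simulate_cohort(
    spec: SyntheticSpec,
    geometry: ChamberGeometry | None = None,
    flow: FlowCondition | None = None,
    measurement: str = "assay",
    tissue: str = "stroma",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a mouse cohort with per-animal biomarkers and nodule counts.

    Per animal: draw true (tau50, k, Pc) uniformly over the spec ranges,
    draw the lung-nodule count from the Poisson log-linear link, then
    produce the *measured* (tau50, Pc) either exactly (``measurement=
    'exact'``) or through the full virtual assay — chamber experiment,
    binning, and two-population deconvolution against the spec host
    (``measurement='assay'``, the default).

    Returns ``(cohort, truth)``; the cohort table has columns
    ``sample_id, tissue, tau50, pc, nodules`` and is what the risk layer
    consumes, while the truth table holds the generating parameters for
    recovery checks.
    """
    from .deconvolution import fit_mixture  # lazy: avoids an import cycle
    from .profiles import build_profile

    if measurement not in ("assay", "exact"):
        raise ValueError("measurement must be 'assay' or 'exact'")
    geometry = geometry or default_geometry()
    flow = flow or default_flow(geometry)

    g_truth = _op_rng(spec.seed, "cohort-truth")
    g_nodules = _op_rng(spec.seed, "cohort-nodules")
    g_assay = _op_rng(spec.seed, "cohort-assay")

    n = spec.n_samples
    true_tau50 = g_truth.uniform(*spec.tau50_range, size=n)
    true_k = g_truth.uniform(*spec.k_range, size=n)
    true_pc = g_truth.uniform(*spec.pc_range, size=n)
    log_mu = (
        spec.baseline_log_nodules
        + spec.coef_tau50 * (true_tau50 - 100.0)
        + spec.coef_pc * (true_pc - 0.3)
    )
    nodules = g_nodules.poisson(np.exp(log_mu))

    rows = []
    truth_rows = []
    for i in range(n):
        sid = f"animal_{i:03d}"
        if measurement == "exact":
            meas_tau50, meas_pc = float(true_tau50[i]), float(true_pc[i])
        else:
            cancer_i = weibull_from_tau50(float(true_tau50[i]), float(true_k[i]))
            pre, post = simulate_experiment(
                cancer=cancer_i, host=spec.host, Pc=float(true_pc[i]),
                n_cells=spec.n_cells, geometry=geometry, flow=flow,
                rng=g_assay, slide_id=sid,
            )
            profile = build_profile(pre, post, geometry, flow)
            fit = fit_mixture(profile, spec.host)
            meas_tau50, meas_pc = fit.tau50_cancer, fit.Pc
        rows.append(
            {
                "sample_id": sid,
                "tissue": tissue,
                "tau50": meas_tau50,
                "pc": meas_pc,
                "nodules": int(nodules[i]),
            }
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "true_tau50": float(true_tau50[i]),
                "true_k": float(true_k[i]),
                "true_pc": float(true_pc[i]),
                "expected_nodules": float(np.exp(log_mu[i])),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
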