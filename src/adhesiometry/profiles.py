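"""Adhesion profiles and one-population Weibull detachment fits.

The assay images adherent nuclei before and after a 3-minute shear
exposure, assigns each cell to one of the equal-length chamber bins, and
records the fraction of cells remaining per bin.  Plotting that fraction
against the shear at each bin center yields the *adhesion profile*, which
is fit to a Weibull survival model

    S(tau) = exp(-(tau / lambda)**k)

with scale ``lambda`` (dyn/cm^2) and shape ``k``.  Adhesion strength is
summarized by the quantiles tau50 = lambda * (-ln 0.5)**(1/k) (shear at
which half the cells have detached) and tau75 = lambda * (-ln 0.75)**(1/k)
(shear at which a quarter have detached); tau75 < tau50 always.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .chamber import ChamberGeometry, FlowCondition, bin_boundaries, bin_edges

logger = logging.getLogger(__name__)

__all__ = [
    "CellObservationSet",
    "AdhesionProfile",
    "WeibullParams",
    "ConfidenceBands",
    "FitError",
    "weibull_survival",
    "build_profile",
    "fit_weibull",
    "tau_quantile",
    "average_replicates",
    "confidence_bounds",
    "track_metrics",
]


class FitError(RuntimeError):
    """Raised when a curve fit cannot produce a usable result."""


def weibull_survival(tau, lam: float, k: float):
    """Weibull survival fraction ``exp(-(tau/lam)**k)``."""
    tau = np.asarray(tau, dtype=float)
    return np.exp(-((tau / lam) ** k))


@dataclass(frozen=True)
class CellObservationSet:
    """Per-slide, per-replicate nucleus positions for one imaging phase.

    ``positions`` are along-channel coordinates in cm, measured from the
    chamber throat (same axis as :mod:`adhesiometry.chamber`).
    """

    slide_id: str
    replicate_id: str
    phase: str  # "pre" | "post"
    positions: np.ndarray

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        object.__setattr__(
            self, "positions", np.asarray(self.positions, dtype=float).ravel()
        )


@dataclass(frozen=True)
class AdhesionProfile:
    """Binned survival-vs-shear curve.

    Attributes
    ----------
    tau : ndarray
        Shear at each bin center (dyn/cm^2), strictly decreasing with
        position along the chamber.
    n_pre, n_post : ndarray
        Cell counts per bin before / after shear.
    S : ndarray
        Fraction remaining per bin, clamped to [0, 1]; NaN for bins with
        no pre-shear cells (those bins are excluded from fitting).
    sem : ndarray or None
        Per-bin standard error of the mean, populated for replicate
        averages.
    """

    tau: np.ndarray
    n_pre: np.ndarray
    n_post: np.ndarray
    S: np.ndarray
    slide_id: str = ""
    replicate_id: str = ""
    sem: np.ndarray | None = None
    n_clamped: int = 0

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if np.any(tau <= 0):
            raise ValueError("bin-center shear must be strictly positive")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "n_pre", np.asarray(self.n_pre, dtype=float))
        object.__setattr__(self, "n_post", np.asarray(self.n_post, dtype=float))
        object.__setattr__(self, "S", np.asarray(self.S, dtype=float))

    @property
    def usable(self) -> np.ndarray:
        """Mask of bins that carry information (n_pre > 0)."""
        return self.n_pre > 0

    @classmethod
    def from_fractions(
        cls, tau, S, sem=None, slide_id: str = "", replicate_id: str = ""
    ) -> "AdhesionProfile":
        """Build a profile directly from per-bin survival fractions."""
        tau = np.asarray(tau, dtype=float)
        S = np.clip(np.asarray(S, dtype=float), 0.0, 1.0)
        ones = np.ones_like(tau)
        return cls(
            tau=tau, n_pre=ones, n_post=S, S=S, sem=sem,
            slide_id=slide_id, replicate_id=replicate_id,
        )


@dataclass(frozen=True)
class WeibullParams:
    """Fitted one-population Weibull survival model.

    ``cov`` is the 2x2 covariance of (lambda, k) from the Jacobian at the
    least-squares optimum; ``n_points`` and ``residual_var`` feed the
    confidence/prediction bands.
    """

    lam: float
    k: float
    r_squared: float = math.nan
    cov: np.ndarray | None = None
    n_points: int = 0
    residual_var: float = math.nan
    failed: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError(f"lam and k must be positive (got {self.lam}, {self.k})")

    @property
    def tau50(self) -> float:
        """Shear at which 50% of cells detach."""
        return tau_quantile(self, 0.5)

    @property
    def tau75(self) -> float:
        """Shear at which 25% of cells detach (survival 0.75)."""
        return tau_quantile(self, 0.75)

    def survival(self, tau):
        return weibull_survival(tau, self.lam, self.k)


def tau_quantile(params: WeibullParams, surviving_fraction: float) -> float:
    """Shear (dyn/cm^2) at which the model survival equals the given fraction.

    ``lambda * (-ln(f))**(1/k)``; strictly decreasing in ``f``, so
    tau75 < tau50 for every valid parameter pair.
    """
    f = float(surviving_fraction)
    if not 0.0 < f < 1.0:
        raise ValueError(f"surviving_fraction must be in (0, 1), got {f}")
    return params.lam * (-math.log(f)) ** (1.0 / params.k)


def build_profile(
    pre: CellObservationSet,
    post: CellObservationSet,
    geometry: ChamberGeometry,
    flow: FlowCondition,
) -> AdhesionProfile:
    """Bin pre/post cell positions into an adhesion profile.

    Cells are assigned to half-open bins [start, end) tiling the imaged
    region (last bin closed); positions outside the region are discarded.
    ``S = n_post / n_pre`` per occupied bin, clamped to [0, 1]: cells can
    drift into a bin during shearing, so post > pre is tolerated but the
    stored fraction never exceeds 1.
    """
    if pre.phase != "pre" or post.phase != "post":
        raise ValueError("expected a (pre, post) pair of observation sets")
    if (pre.slide_id, pre.replicate_id) != (post.slide_id, post.replicate_id):
        raise ValueError(
            f"mismatched slide/replicate ids: {pre.slide_id}/{pre.replicate_id} "
            f"vs {post.slide_id}/{post.replicate_id}"
        )
    edges = bin_boundaries(geometry)
    _, tau = bin_edges(geometry, flow)

    def count(positions: np.ndarray) -> np.ndarray:
        inside = (positions >= edges[0]) & (positions <= edges[-1])
        idx = np.minimum(
            np.searchsorted(edges, positions[inside], side="right") - 1,
            geometry.n_bins - 1,
        )
        return np.bincount(idx, minlength=geometry.n_bins).astype(float)

    n_pre = count(pre.positions)
    n_post = count(post.positions)
    if not np.any(n_pre > 0):
        raise FitError("empty profile: no pre-shear cells inside the imaged region")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_pre > 0, n_post / np.maximum(n_pre, 1e-300), np.nan)
    n_clamped = int(np.sum(raw > 1.0))
    if n_clamped:
        logger.warning(
            "slide %s/%s: %d bin(s) gained cells during shearing; S clamped to 1",
            pre.slide_id, pre.replicate_id, n_clamped,
        )
    S = np.clip(raw, 0.0, 1.0)
    return AdhesionProfile(
        tau=tau, n_pre=n_pre, n_post=n_post, S=S,
        slide_id=pre.slide_id, replicate_id=pre.replicate_id,
        n_clamped=n_clamped,
    )


def _initial_lambda(tau: np.ndarray, S: np.ndarray) -> float:
    """Shear at which empirical survival first crosses 0.5.

    Profiles run from high shear (low S) to low shear (high S); scan in
    increasing-shear order and interpolate the 0.5 crossing.  Falls back to
    the median bin shear when S never crosses 0.5.
    """
    order = np.argsort(tau)
    t, s = tau[order], S[order]
    above = s >= 0.5
    if above.all() or not above.any():
        return float(np.median(t))
    # last index (in increasing tau) where S >= 0.5
    i = int(np.max(np.nonzero(above)[0]))
    if i + 1 >= len(t):
        return float(t[i])
    s0, s1, t0, t1 = s[i], s[i + 1], t[i], t[i + 1]
    if s0 == s1:
        return float(t0)
    return float(t0 + (0.5 - s0) * (t1 - t0) / (s1 - s0))


def fit_weibull(
    profile: AdhesionProfile,
    weighted: bool = False,
) -> WeibullParams:
    """Least-squares fit of the one-population Weibull survival model.

    Unweighted least squares on the per-bin fractions by default, matching
    common curve-fitting-toolbox practice for binned detachment data; set
    ``weighted=True`` to weight residuals by sqrt(n_pre).

    Raises
    ------
    FitError
        If fewer than 3 usable bins exist or the data carry no detachment
        information (e.g. constant survival).
    """
    mask = profile.usable & np.isfinite(profile.S)
    tau = profile.tau[mask]
    S = profile.S[mask]
    if len(np.unique(tau)) < 3:
        raise FitError(
            f"need >= 3 usable bins with distinct shear, got {len(np.unique(tau))}"
        )
    sstot = float(np.sum((S - S.mean()) ** 2))
    if sstot == 0.0:
        raise FitError("constant survival across bins: no detachment information")

    w = np.sqrt(profile.n_pre[mask]) if weighted else np.ones_like(S)
    lam0 = _initial_lambda(tau, S)
    k0 = 2.0
    lam_hi = 10.0 * float(tau.max())
    bounds = ([1e-9, 1e-9], [lam_hi, 20.0])
    lam0 = min(max(lam0, bounds[0][0] * 2), lam_hi * 0.99)

    def resid(p):
        return w * (weibull_survival(tau, p[0], p[1]) - S)

    sol = optimize.least_squares(
        resid, x0=[lam0, k0], bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    lam, k = float(sol.x[0]), float(sol.x[1])
    res = weibull_survival(tau, lam, k) - S
    ssres = float(np.sum(res**2))
    r2 = 1.0 - ssres / sstot
    n = len(S)
    dof = max(n - 2, 1)
    s2 = ssres / dof

    # covariance from the Jacobian at the optimum (Gauss-Newton approximation)
    J = sol.jac
    try:
        JTJ_inv = np.linalg.inv(J.T @ J)
        cov = s2 * JTJ_inv
    except np.linalg.LinAlgError:
        cov = None

    failed = not sol.success
    message = sol.message if failed else ""
    at_bound = lam >= lam_hi * (1 - 1e-9) or k >= 20.0 * (1 - 1e-9)
    if at_bound:
        failed = True
        message = f"parameters at bounds: lam={lam:.4g}, k={k:.4g}"
    if r2 < 0:
        failed = True
        message = message or f"pathological fit (R^2 = {r2:.3g})"

    return WeibullParams(
        lam=lam, k=k, r_squared=r2, cov=cov, n_points=n,
        residual_var=s2, failed=failed, message=message,
    )


def average_replicates(
    profiles: list[AdhesionProfile],
    fits: list[WeibullParams] | None = None,
    r2_threshold: float = 0.5,
    weighted: bool = False,
) -> tuple[AdhesionProfile, WeibullParams, list[int]]:
    """QC-filter technical replicates, average them, and refit.

    Replicates whose one-population fit has R^2 <= ``r2_threshold`` are
    excluded; the survivors are averaged per bin (simple mean of S, with
    the standard error of the mean recorded) and the averaged profile is
    refit.

    Returns ``(averaged_profile, fit_of_average, kept_indices)``.

    Raises
    ------
    FitError
        If no replicate passes QC; the message lists per-replicate R^2.
    """
    if not profiles:
        raise ValueError("need at least one replicate")
    if fits is None:
        fits = []
        for p in profiles:
            try:
                fits.append(fit_weibull(p, weighted=weighted))
            except FitError:
                fits.append(None)
    r2s = [f.r_squared if f is not None else math.nan for f in fits]
    kept = [
        i for i, f in enumerate(fits)
        if f is not None and not f.failed and f.r_squared > r2_threshold
    ]
    excluded = [i for i in range(len(profiles)) if i not in kept]
    for i in excluded:
        logger.info(
            "replicate %s/%s excluded by QC (R^2 = %s)",
            profiles[i].slide_id, profiles[i].replicate_id,
            f"{r2s[i]:.3f}" if math.isfinite(r2s[i]) else "fit failed",
        )
    if not kept:
        raise FitError(
            "no replicate passed QC (R^2 > "
            f"{r2_threshold}); per-replicate R^2 = "
            + ", ".join(f"{r:.3f}" if math.isfinite(r) else "failed" for r in r2s)
        )
    tau = profiles[kept[0]].tau
    for i in kept[1:]:
        if not np.allclose(profiles[i].tau, tau):
            raise ValueError("replicates were binned on different shear grids")
    stack = np.vstack([profiles[i].S for i in kept])
    mean = np.nanmean(stack, axis=0)
    m = stack.shape[0]
    if m > 1:
        sem = np.nanstd(stack, axis=0, ddof=1) / math.sqrt(m)
    else:
        sem = np.zeros_like(mean)
    n_pre = np.vstack([profiles[i].n_pre for i in kept]).sum(axis=0)
    n_post = np.vstack([profiles[i].n_post for i in kept]).sum(axis=0)
    averaged = AdhesionProfile(
        tau=tau, n_pre=n_pre, n_post=n_post, S=mean, sem=sem,
        slide_id=profiles[kept[0]].slide_id, replicate_id="averaged",
    )
    fit = fit_weibull(averaged, weighted=weighted)
    return averaged, fit, kept


@dataclass(frozen=True)
class ConfidenceBands:
    """Pointwise 95% (by default) bands around a fitted survival curve."""

    tau: np.ndarray
    fitted: np.ndarray
    conf_lo: np.ndarray
    conf_hi: np.ndarray
    pred_lo: np.ndarray
    pred_hi: np.ndarray
    tau75_ci: tuple[float, float]
    level: float


def _quantile_gradient(params: WeibullParams, f: float) -> np.ndarray:
    """Gradient of tau_f = lam * (-ln f)**(1/k) with respect to (lam, k)."""
    c = -math.log(f)
    d_lam = c ** (1.0 / params.k)
    d_k = params.lam * c ** (1.0 / params.k) * math.log(c) * (-1.0 / params.k**2)
    return np.array([d_lam, d_k])


def confidence_bounds(
    params: WeibullParams,
    profile: AdhesionProfile,
    level: float = 0.95,
    tau_grid: np.ndarray | None = None,
) -> ConfidenceBands:
    """Delta-method confidence and prediction bands, plus a tau75 CI.

    The confidence band propagates the parameter covariance through the
    survival model to first order; the prediction band additionally adds
    the residual variance.  Critical values use Student's t with n-2
    degrees of freedom, matching standard nonlinear-regression intervals.
    """
    if params.cov is None or not np.all(np.isfinite(params.cov)):
        raise FitError("parameter covariance unavailable; bounds cannot be computed")
    tau = (
        np.asarray(tau_grid, dtype=float)
        if tau_grid is not None
        else profile.tau[profile.usable]
    )
    dof = max(params.n_points - 2, 1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    lam, k = params.lam, params.k
    z = tau / lam
    Sfit = np.exp(-(z**k))
    # dS/dlam, dS/dk at the optimum
    with np.errstate(divide="ignore", invalid="ignore"):
        d_lam = Sfit * (z**k) * k / lam
        d_k = np.where(z > 0, -Sfit * (z**k) * np.log(z), 0.0)
    G = np.vstack([d_lam, d_k])  # (2, m)
    var_fit = np.einsum("im,ij,jm->m", G, params.cov, G)
    var_fit = np.maximum(var_fit, 0.0)
    half_conf = tcrit * np.sqrt(var_fit)
    s2 = params.residual_var if math.isfinite(params.residual_var) else 0.0
    half_pred = tcrit * np.sqrt(var_fit + s2)

    g = _quantile_gradient(params, 0.75)
    var_t75 = float(g @ params.cov @ g)
    half_t75 = tcrit * math.sqrt(max(var_t75, 0.0))
    t75 = params.tau75
    return ConfidenceBands(
        tau=tau,
        fitted=Sfit,
        conf_lo=np.clip(Sfit - half_conf, 0.0, 1.0),
        conf_hi=np.clip(Sfit + half_conf, 0.0, 1.0),
        pred_lo=np.clip(Sfit - half_pred, 0.0, 1.0),
        pred_hi=np.clip(Sfit + half_pred, 0.0, 1.0),
        tau75_ci=(t75 - half_t75, t75 + half_t75),
        level=level,
    )


def track_metrics(
    trajectory: np.ndarray, duration_h: float = 15.0
) -> tuple[float, float]:
    """Migration speed and net displacement from a time-ordered trajectory.

    Speed is total path length divided by the runtime (default 15 h);
    displacement is the Euclidean distance between first and last point.
    Positions are (n_points, n_dims) in um; returns (um/h, um).
    """
    xy = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 time points to compute track metrics")
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    steps = np.diff(xy, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    disp = float(np.linalg.norm(xy[-1] - xy[0]))
    return path / duration_h, disp
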