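"""Divergent parallel-plate flow chamber (dPPFC) model.

The chamber's side walls diverge exponentially, so the channel width grows
from ``w_min`` at the inlet to ``10 * w_min`` over the length ``L_max``:

    w(L) = w_min * exp(ln(10) * L / L_max)

Under fully developed laminar flow between parallel plates the wall shear
stress at position ``L`` is

    tau(L) = 6 * Q * mu / (w(L) * h**2)

so a single perfusion exposes cells seeded along the chamber to a
continuously (exponentially) decreasing shear.  All computation is in CGS
units: cm, s, poise, dyn/cm^2.

The V-shaped outlet beyond ``L_max``, where shear decays to zero, is not
modelled; analysis is restricted to the imaged region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChamberGeometry",
    "FlowCondition",
    "channel_width",
    "shear_at_position",
    "flow_for_max_shear",
    "bin_edges",
    "um_to_cm",
    "cm_to_um",
    "ul_per_s_to_cm3_per_s",
]

#: 10-fold widening of the channel over its divergent length.
WIDENING_FACTOR = 10.0

LN_WIDENING = math.log(WIDENING_FACTOR)


def um_to_cm(x: float) -> float:
    """Convert micrometers to centimeters."""
    return x / 1e4


def cm_to_um(x: float) -> float:
    """Convert centimeters to micrometers."""
    return x * 1e4


def ul_per_s_to_cm3_per_s(q: float) -> float:
    """Convert a flow rate in uL/s to cm^3/s."""
    return q / 1e3


@dataclass(frozen=True)
class ChamberGeometry:
    """Physical description of the divergent chamber and its imaged region.

    Parameters
    ----------
    w_min : float
        Channel width at the narrowest point (cm).
    L_max : float
        Length between the narrowest and widest points (cm).
    h : float
        Channel height (gasket thickness) in cm.
    imaged_region_length : float
        Length of the scanned region along the channel (cm).
    imaged_region_offset : float
        Position of the scan start relative to the narrowest point (cm).
    n_bins : int
        Number of equal-sized bins the imaged region is divided into.

    Notes
    -----
    The defaults (see :func:`default_geometry`) correspond to a 2.1 mm
    throat, a 127 um gasket, and a 61-bin imaged region of 61 x 775 um =
    47.275 mm starting at the throat.  The device drawing is not fully
    dimensioned in public sources, so the throat width and divergent length
    are documented assumptions; every value is overridable.
    """

    w_min: float
    L_max: float
    h: float
    imaged_region_length: float
    imaged_region_offset: float = 0.0
    n_bins: int = 61

    def __post_init__(self) -> None:
        if self.w_min <= 0 or self.L_max <= 0 or self.h <= 0:
            raise ValueError(
                "w_min, L_max and h must be positive "
                f"(got {self.w_min}, {self.L_max}, {self.h})"
            )
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.imaged_region_offset < 0:
            raise ValueError("imaged_region_offset must be >= 0")
        if self.imaged_region_length <= 0:
            raise ValueError("imaged_region_length must be > 0")
        end = self.imaged_region_offset + self.imaged_region_length
        if end > self.L_max * (1 + 1e-12):
            raise ValueError(
                f"imaged region [{self.imaged_region_offset}, {end}] cm extends "
                f"beyond the divergent section (L_max = {self.L_max} cm)"
            )


@dataclass(frozen=True)
class FlowCondition:
    """Perfusion parameters: flow rate and viscosity.

    Exactly one of ``Q`` (cm^3/s) or ``tau_max`` (dyn/cm^2, the wall shear
    at the narrowest point) is required at construction time via
    :meth:`from_flow_rate` / :meth:`from_max_shear`; the stored pair is
    always mutually consistent.
    """

    Q: float
    mu: float
    tau_max: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.Q <= 0 or self.mu <= 0:
            raise ValueError(f"Q and mu must be positive (got {self.Q}, {self.mu})")
        if self.tau_max is not None and self.tau_max <= 0:
            raise ValueError("tau_max must be positive when given")

    @classmethod
    def from_flow_rate(cls, Q: float, mu: float) -> "FlowCondition":
        return cls(Q=Q, mu=mu, tau_max=None)

    @classmethod
    def from_max_shear(
        cls, geometry: ChamberGeometry, mu: float, tau_max: float
    ) -> "FlowCondition":
        Q = flow_for_max_shear(geometry, mu, tau_max)
        return cls(Q=Q, mu=mu, tau_max=tau_max)


def default_geometry(n_bins: int = 61) -> ChamberGeometry:
    """Default chamber: 2.1 mm throat, 127 um height, 61 x 775 um bins."""
    bin_length = um_to_cm(775.0)
    length = n_bins * bin_length
    return ChamberGeometry(
        w_min=0.21,
        L_max=length,
        h=um_to_cm(127.0),
        imaged_region_length=length,
        imaged_region_offset=0.0,
        n_bins=n_bins,
    )


def channel_width(geometry: ChamberGeometry, L):
    """Channel width (cm) at position ``L`` cm downstream of the throat.

    ``w(L) = w_min * exp(ln(10) * L / L_max)``; strictly increasing, with
    ``w(0) = w_min`` and ``w(L_max) = 10 * w_min``.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0) or np.any(L > geometry.L_max * (1 + 1e-12)):
        raise ValueError(
            f"position must lie in [0, {geometry.L_max}] cm (the V-shaped "
            "outlet beyond L_max is not modelled)"
        )
    out = geometry.w_min * np.exp(LN_WIDENING * L / geometry.L_max)
    return float(out) if out.ndim == 0 else out


def shear_at_position(geometry: ChamberGeometry, flow: FlowCondition, L):
    """Wall shear stress (dyn/cm^2) at position ``L`` (cm).

    ``tau(L) = 6 Q mu / (w(L) h^2)``; strictly decreasing in ``L`` because
    the width grows exponentially.
    """
    w = channel_width(geometry, L)
    return 6.0 * flow.Q * flow.mu / (w * geometry.h**2)


def flow_for_max_shear(
    geometry: ChamberGeometry, mu: float, tau_max: float
) -> float:
    """Flow rate (cm^3/s) producing shear ``tau_max`` at the throat (L=0)."""
    if tau_max <= 0:
        raise ValueError(f"tau_max must be positive, got {tau_max}")
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    return tau_max * geometry.w_min * geometry.h**2 / (6.0 * mu)


def bin_boundaries(geometry: ChamberGeometry) -> np.ndarray:
    """``n_bins + 1`` bin edges (cm) tiling the imaged region equally.

    Bins are half-open ``[start, end)``; the last bin is closed.
    """
    start = geometry.imaged_region_offset
    stop = start + geometry.imaged_region_length
    return np.linspace(start, stop, geometry.n_bins + 1)


def bin_edges(
    geometry: ChamberGeometry, flow: FlowCondition
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-center positions (cm) and shear (dyn/cm^2) for every imaged bin.

    Returns
    -------
    centers, tau : ndarray
        ``n_bins`` bin-center positions and the wall shear stress evaluated
        at each center; ``tau`` is strictly decreasing along the chamber.
    """
    edges = bin_boundaries(geometry)
    centers = 0.5 * (edges[:-1] + edges[1:])
    tau = shear_at_position(geometry, flow, centers)
    return centers, np.asarray(tau, dtype=float)
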