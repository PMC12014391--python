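"""Configuration, tabular I/O and run manifests.

All tabular data are plain CSV with explicit header schemas; fitted
parameters are JSON; configuration is YAML or JSON.  Readers validate
schemas strictly — a missing column or a silently coercible type (e.g. a
non-integer nodule count) is an error with row/column context, never a
guess.  Floats in machine-readable outputs are written with ``repr``
(17 significant digits) so byte-identical reruns imply identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chamber import (
    ChamberGeometry,
    FlowCondition,
    ul_per_s_to_cm3_per_s,
    um_to_cm,
)
from .profiles import AdhesionProfile, CellObservationSet, WeibullParams

__all__ = [
    "load_config",
    "read_cells_csv",
    "read_cohort_csv",
    "write_profile_csv",
    "read_profile_csv",
    "write_fit_json",
    "read_fit_json",
    "RunManifest",
]

CELLS_POSITION_COLUMNS = ["slide_id", "replicate_id", "phase", "pos_um"]
CELLS_BINNED_COLUMNS = ["slide_id", "replicate_id", "bin_index", "n_pre", "n_post"]
COHORT_COLUMNS = ["sample_id", "tissue", "tau50", "pc", "nodules"]


class SchemaError(ValueError):
    """A tabular input violates its declared schema."""


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_config(path: str | Path) -> tuple[ChamberGeometry, FlowCondition, dict]:
    """Read a chamber/flow configuration (YAML or JSON).

    Required keys: ``w_min_um``, ``L_max_um``, ``h_um``,
    ``imaged_region_length_um``, ``imaged_region_offset_um``, ``n_bins``,
    ``viscosity_poise`` and exactly one of ``flow_rate_ul_per_s`` or
    ``tau_max_dyn_cm2``.  Returns the geometry, the flow condition, and
    any remaining keys untouched.
    """
    cfg = _load_mapping(path)
    required = [
        "w_min_um", "L_max_um", "h_um", "imaged_region_length_um",
        "imaged_region_offset_um", "n_bins", "viscosity_poise",
    ]
    missing = [k for k in required if k not in cfg]
    if missing:
        raise SchemaError(f"config {path}: missing keys {missing}")
    has_q = "flow_rate_ul_per_s" in cfg
    has_tau = "tau_max_dyn_cm2" in cfg
    if has_q == has_tau:
        raise SchemaError(
            f"config {path}: exactly one of flow_rate_ul_per_s or "
            "tau_max_dyn_cm2 is required"
        )
    geometry = ChamberGeometry(
        w_min=um_to_cm(float(cfg["w_min_um"])),
        L_max=um_to_cm(float(cfg["L_max_um"])),
        h=um_to_cm(float(cfg["h_um"])),
        imaged_region_length=um_to_cm(float(cfg["imaged_region_length_um"])),
        imaged_region_offset=um_to_cm(float(cfg["imaged_region_offset_um"])),
        n_bins=int(cfg["n_bins"]),
    )
    mu = float(cfg["viscosity_poise"])
    if has_tau:
        flow = FlowCondition.from_max_shear(
            geometry, mu=mu, tau_max=float(cfg["tau_max_dyn_cm2"])
        )
    else:
        flow = FlowCondition.from_flow_rate(
            Q=ul_per_s_to_cm3_per_s(float(cfg["flow_rate_ul_per_s"])), mu=mu
        )
    extras = {
        k: v
        for k, v in cfg.items()
        if k not in required + ["flow_rate_ul_per_s", "tau_max_dyn_cm2"]
    }
    return geometry, flow, extras


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} (have {list(df.columns)})")


def read_cells_csv(path: str | Path) -> dict[tuple[str, str], dict[str, CellObservationSet]]:
    """Read per-cell positions grouped by (slide, replicate) and phase.

    Schema: ``slide_id,replicate_id,phase,pos_um`` (one row per detected
    nucleus; phase is 'pre' or 'post'; positions in um from the throat).
    """
    df = pd.read_csv(path, dtype={"slide_id": str, "replicate_id": str, "phase": str})
    _require_columns(df, CELLS_POSITION_COLUMNS, path)
    bad = ~df["phase"].isin(["pre", "post"])
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(
            f"{path}: row {row}: phase must be 'pre' or 'post', "
            f"got {df['phase'].iloc[row]!r}"
        )
    out: dict[tuple[str, str], dict[str, CellObservationSet]] = {}
    for (slide, rep, phase), grp in df.groupby(
        ["slide_id", "replicate_id", "phase"], sort=True
    ):
        obs = CellObservationSet(
            slide_id=slide,
            replicate_id=rep,
            phase=phase,
            positions=um_to_cm(1.0) * grp["pos_um"].to_numpy(dtype=float),
        )
        out.setdefault((slide, rep), {})[phase] = obs
    return out


def read_binned_cells_csv(
    path: str | Path, geometry, flow
) -> dict[tuple[str, str], AdhesionProfile]:
    """Read pre-binned counts into adhesion profiles.

    Schema: ``slide_id,replicate_id,bin_index,n_pre,n_post`` with one row
    per bin; bin indices must be valid for the supplied geometry.  Counts
    must be non-negative integers.
    """
    from .chamber import bin_edges

    df = pd.read_csv(path, dtype={"slide_id": str, "replicate_id": str})
    _require_columns(df, CELLS_BINNED_COLUMNS, path)
    for col in ("bin_index", "n_pre", "n_post"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 0)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(
                f"{path}: row {row}: {col} must be a non-negative integer, "
                f"got {df[col].iloc[row]!r}"
            )
        df[col] = vals.astype(int)
    if (df["bin_index"] >= geometry.n_bins).any():
        raise SchemaError(f"{path}: bin_index exceeds n_bins-1 ({geometry.n_bins - 1})")
    _, tau = bin_edges(geometry, flow)
    out: dict[tuple[str, str], AdhesionProfile] = {}
    for (slide, rep), grp in df.groupby(["slide_id", "replicate_id"], sort=True):
        n_pre = np.zeros(geometry.n_bins)
        n_post = np.zeros(geometry.n_bins)
        n_pre[grp["bin_index"]] = grp["n_pre"]
        n_post[grp["bin_index"]] = grp["n_post"]
        with np.errstate(divide="ignore", invalid="ignore"):
            S = np.where(n_pre > 0, np.clip(n_post / np.maximum(n_pre, 1), 0, 1), np.nan)
        out[(slide, rep)] = AdhesionProfile(
            tau=tau, n_pre=n_pre, n_post=n_post, S=S,
            slide_id=slide, replicate_id=rep,
        )
    return out


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table ``sample_id,tissue,tau50,pc,nodules``.

    Nodule counts must be non-negative integers; fractional or negative
    values are rejected with their row index.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "tissue": str})
    _require_columns(df, COHORT_COLUMNS, path)
    nod = pd.to_numeric(df["nodules"], errors="coerce")
    bad = nod.isna() | (nod != nod.round()) | (nod < 0)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(
            f"{path}: row {row}: nodules must be a non-negative integer, "
            f"got {df['nodules'].iloc[row]!r}"
        )
    df["nodules"] = nod.astype(int)
    df["tau50"] = pd.to_numeric(df["tau50"])
    df["pc"] = pd.to_numeric(df["pc"])
    if (df["tau50"] <= 0).any() or ((df["pc"] < 0) | (df["pc"] > 1)).any():
        raise SchemaError(f"{path}: tau50 must be > 0 and pc within [0, 1]")
    return df


def write_profile_csv(profile: AdhesionProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "bin_index": np.arange(len(profile.tau)),
            "tau_dyn_cm2": [repr(float(v)) for v in profile.tau],
            "n_pre": profile.n_pre.astype(int),
            "n_post": profile.n_post.astype(int),
            "S": [repr(float(v)) for v in profile.S],
        }
    )
    if profile.sem is not None:
        df["sem"] = [repr(float(v)) for v in profile.sem]
    df.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> AdhesionProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["bin_index", "tau_dyn_cm2", "n_pre", "n_post", "S"], path)
    return AdhesionProfile(
        tau=df["tau_dyn_cm2"].to_numpy(dtype=float),
        n_pre=df["n_pre"].to_numpy(dtype=float),
        n_post=df["n_post"].to_numpy(dtype=float),
        S=df["S"].to_numpy(dtype=float),
        sem=df["sem"].to_numpy(dtype=float) if "sem" in df.columns else None,
    )


def write_fit_json(fit, path: str | Path, extra: dict | None = None) -> None:
    """Write a one-population or mixture fit as a JSON report."""
    from .deconvolution import MixtureFit

    if isinstance(fit, MixtureFit):
        payload = {
            "model": "two_population_weibull",
            "pc": fit.Pc,
            "lambda": fit.cancer.lam,
            "k": fit.cancer.k,
            "tau50": fit.tau50_cancer,
            "host_lambda": fit.host.lam,
            "host_k": fit.host.k,
            "r_squared": fit.r_squared,
            "failed": fit.failed,
            "label_ambiguous": fit.label_ambiguous,
        }
    else:
        payload = {
            "model": "one_population_weibull",
            "lambda": fit.lam,
            "k": fit.k,
            "tau50": fit.tau50,
            "tau75": fit.tau75,
            "r_squared": fit.r_squared,
            "failed": fit.failed,
        }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_fit_json(path: str | Path) -> WeibullParams:
    """Read a one-population fit report back into parameters."""
    payload = json.loads(Path(path).read_text())
    return WeibullParams(
        lam=float(payload["lambda"]),
        k=float(payload["k"]),
        r_squared=float(payload.get("r_squared", float("nan"))),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for a pipeline run.

    Identical config + input checksums + seed imply identical numerical
    outputs (the pipeline is deterministic given these).
    """

    seed: int | None = None
    config_hash: str = ""
    package_version: str = ""
    input_checksums: dict = field(default_factory=dict)
    output_paths: list = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)

    def record_config(self, path: str | Path) -> None:
        self.config_hash = _sha256(Path(path))

    def record_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_checksums[str(p)] = _sha256(p)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.stage_seconds[name] = time.perf_counter() - self.t0
                return False

        return _Timer()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
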