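"""Configuration files, electrode tables, and scalp-map gridding.

Configuration is YAML (JSON is a YAML subset and parses too)::

    units: {length: cm}
    radii: [7.9, 8.0, 8.5, 9.0]
    conductivities:
      brain: 0.33
      csf_multiplier: 5.0
      skull_divisor: 20.0
      scalp_multiplier: 1.0
    dipole:
      position: [0.0, 0.0, 7.8]     # in the declared length unit
      moment: [0.0, 0.0, 1.0e-7]    # A*m
    series: {n_max: 5000, rel_tol: 1.0e-12, consecutive_small: 10}

``conductivities`` may instead be a flat list of four S/m values.  Electrode
files are CSV with header ``label,x,y,z`` in the declared length unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .coefficients import SeriesControl
from .model import (
    Dipole,
    FourSphereError,
    HeadModel,
    ParameterError,
    make_head_model,
    SIGMA_BRAIN,
)

__all__ = [
    "RunConfig",
    "ScalpMap",
    "load_config",
    "read_electrodes",
    "write_potentials",
    "scalp_map",
]


class ConfigError(FourSphereError, ValueError):
    """Configuration file is malformed or inconsistent."""


class ElectrodeFileError(FourSphereError, ValueError):
    """Electrode CSV is malformed; the message names the offending line."""


_DEFAULT_CONFIG: dict[str, Any] = {
    "units": {"length": "cm"},
    "radii": [7.9, 8.0, 8.5, 9.0],
    "conductivities": {
        "brain": SIGMA_BRAIN,
        "csf_multiplier": 5.0,
        "skull_divisor": 20.0,
        "scalp_multiplier": 1.0,
    },
    "dipole": {"position": [0.0, 0.0, 7.8], "moment": [0.0, 0.0, 1.0e-7]},
    "series": {"n_max": 5000, "rel_tol": 1e-12, "consecutive_small": 10},
}


@dataclass(frozen=True)
class RunConfig:
    """Parsed configuration: model, series control, optional dipole, units."""

    model: HeadModel
    series: SeriesControl
    dipole: Dipole | None
    length_unit: str = "m"
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def length_scale(self) -> float:
        return {"m": 1.0, "cm": 1e-2, "mm": 1e-3}[self.length_unit]


def _conductivities(spec: Any) -> tuple[float, float, float, float]:
    if isinstance(spec, (list, tuple)):
        if len(spec) != 4:
            raise ConfigError(f"conductivities: expected 4 values, got {len(spec)}")
        return tuple(float(s) for s in spec)
    if isinstance(spec, dict):
        brain = float(spec.get("brain", SIGMA_BRAIN))
        csf = brain * float(spec.get("csf_multiplier", 5.0))
        divisor = float(spec.get("skull_divisor", 20.0))
        if divisor <= 0:
            raise ConfigError(f"skull_divisor must be positive, got {divisor}")
        skull = brain / divisor
        scalp = brain * float(spec.get("scalp_multiplier", 1.0))
        return (brain, csf, skull, scalp)
    raise ConfigError(f"cannot interpret conductivities: {spec!r}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON configuration; ``None`` yields the standard defaults."""
    raw = dict(_DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh)
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = {**raw, **user}
    unit = str(raw.get("units", {}).get("length", "m"))
    if unit not in ("m", "cm", "mm"):
        raise ConfigError(f"unknown length unit {unit!r}")
    try:
        model = make_head_model(raw["radii"], _conductivities(raw["conductivities"]), units=unit)
    except (ParameterError, ConfigError):
        raise
    except FourSphereError as exc:
        raise ConfigError(str(exc)) from exc
    series_raw = raw.get("series", {}) or {}
    series = SeriesControl(
        n_max=int(series_raw.get("n_max", 5000)),
        rel_tol=float(series_raw.get("rel_tol", 1e-12)),
        consecutive_small=int(series_raw.get("consecutive_small", 10)),
    )
    dipole = None
    dip_raw = raw.get("dipole")
    if dip_raw:
        scale = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}[unit]
        pos = tuple(float(v) * scale for v in dip_raw["position"])
        mom = tuple(float(v) for v in dip_raw["moment"])
        dipole = Dipole(position=pos, moment=mom)
    return RunConfig(model=model, series=series, dipole=dipole, length_unit=unit, raw=raw)


def read_electrodes(path: str | Path, length_unit: str = "m") -> pd.DataFrame:
    """Read an electrode CSV (``label,x,y,z``) into SI meters.

    Raises :class:`ElectrodeFileError` naming the first malformed line.
    An empty file (header only) returns an empty frame.
    """
    scale = {"m": 1.0, "cm": 1e-2, "mm": 1e-3}[length_unit]
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ElectrodeFileError(f"{path}: empty file without header") from None
    expected = ["label", "x", "y", "z"]
    if [c.strip().lower() for c in df.columns[:4]] != expected:
        raise ElectrodeFileError(
            f"{path}: header must be 'label,x,y,z', got {list(df.columns)}"
        )
    records = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        label = row.iloc[0]
        if pd.isna(label) or str(label).strip() == "":
            raise ElectrodeFileError(f"{path}: line {line_no}: missing label")
        coords = []
        for col in ("x", "y", "z"):
            cell = row[df.columns[expected.index(col)]]
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise ElectrodeFileError(
                    f"{path}: line {line_no}: cannot parse {col}={cell!r}"
                ) from None
            if not np.isfinite(val):
                raise ElectrodeFileError(
                    f"{path}: line {line_no}: non-finite {col}={cell!r}"
                )
            coords.append(val * scale)
        records.append({"label": str(label).strip(), "x": coords[0], "y": coords[1], "z": coords[2]})
    return pd.DataFrame(records, columns=["label", "x", "y", "z"])


def write_potentials(
    df: pd.DataFrame, values: np.ndarray, path: str | Path, units: str = "V"
) -> pd.DataFrame:
    """Write ``label,x,y,z,potential_V`` (or ``potential_uV``) CSV."""
    out = df.copy()
    if units == "uV":
        out["potential_uV"] = np.asarray(values) * 1e6
    elif units == "V":
        out["potential_V"] = np.asarray(values)
    else:
        raise ParameterError(f"unknown output units {units!r}")
    out.to_csv(path, index=False)
    return out


@dataclass(frozen=True)
class ScalpMap:
    """Gridded potential over the scalp sphere r = r4.

    ``values[i, j]`` is the potential (V) at ``(theta[i], phi[j])``; θ covers
    [0, π], φ covers [0, 2π).
    """

    theta: np.ndarray
    phi: np.ndarray
    values: np.ndarray
    metadata: dict

    def to_dataframe(self, units: str = "V") -> pd.DataFrame:
        tt, pp = np.meshgrid(self.theta, self.phi, indexing="ij")
        col = "potential_uV" if units == "uV" else "potential_V"
        scale = 1e6 if units == "uV" else 1.0
        return pd.DataFrame(
            {
                "theta_rad": tt.ravel(),
                "phi_rad": pp.ravel(),
                col: self.values.ravel() * scale,
            }
        )


def scalp_map(
    model: HeadModel,
    dipole: Dipole,
    ctrl: SeriesControl | None = None,
    n_theta: int = 90,
    n_phi: int = 180,
) -> ScalpMap:
    """Potential on a (θ, φ) grid over the scalp surface."""
    from . import __version__
    from .fields import potential_dipole

    if n_theta < 2 or n_phi < 2:
        raise ParameterError("map resolution must be at least 2 per axis")
    ctrl = ctrl or SeriesControl()
    theta = np.linspace(0.0, np.pi, n_theta)
    phi = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    pts = model.r4 * np.column_stack(
        [
            (np.sin(tt) * np.cos(pp)).ravel(),
            (np.sin(tt) * np.sin(pp)).ravel(),
            np.cos(tt).ravel(),
        ]
    )
    vals = potential_dipole(model, dipole, pts, ctrl).reshape(n_theta, n_phi)
    meta = {
        "radii_m": list(model.radii),
        "conductivities_S_per_m": list(model.conductivities),
        "dipole_position_m": list(dipole.position),
        "dipole_moment_Am": list(dipole.moment),
        "series": {"n_max": ctrl.n_max, "rel_tol": ctrl.rel_tol},
        "version": __version__,
    }
    return ScalpMap(theta=theta, phi=phi, values=vals, metadata=meta)
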