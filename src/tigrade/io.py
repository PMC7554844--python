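"""JSON/CSV readers and writers for the package's domain objects.

Conventions: CSV with a header row and '.' decimal separators, JSON
for nested specs; numeric fields are serialized at full double
precision so write-then-read is the identity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chain_sim import ChainGeometry
from .distributions import DistSpec
from .fgm_grading import GradedStack
from .inverse_est import FDCurve, StrainProfile
from .synthetic_fixtures import IntensityGrid
from .ti_core import TIParams

__all__ = [
    "read_ti_params", "write_ti_params",
    "read_ti_table", "write_ti_table",
    "read_dist_spec", "write_dist_spec",
    "read_intensity_grid", "write_intensity_grid",
    "read_fd_curve", "write_fd_curve",
    "read_chain_geometry", "write_chain_geometry",
    "read_strain_profile", "write_strain_profile",
    "write_stack", "read_stack_params",
]

_TI_FIELDS = ["C1", "C2", "C3", "C4", "C5", "C6", "lambda_star", "K"]


class SchemaError(ValueError):
    """A file does not match the expected column/field layout."""


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_ti_params(path) -> TIParams:
    """Read one TI parameter set from a flat JSON object."""
    d = json.loads(Path(path).read_text())
    missing = [k for k in _TI_FIELDS if k not in d]
    if missing:
        raise SchemaError(f"{path}: missing field(s) {missing}")
    return TIParams(**{k: float(d[k]) for k in _TI_FIELDS}, name=d.get("name", ""))


def write_ti_params(p: TIParams, path) -> None:
    d = {k: getattr(p, k) for k in _TI_FIELDS}
    if p.name:
        d["name"] = p.name
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_ti_table(path) -> dict[str, TIParams]:
    """Read a one-material-per-row CSV table (columns
    name,C1,...,C6,lambda_star,K)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["name"] + _TI_FIELDS, path)
    return {
        str(r["name"]): TIParams(
            **{k: float(r[k]) for k in _TI_FIELDS}, name=str(r["name"])
        )
        for _, r in df.iterrows()
    }


def write_ti_table(materials: dict[str, TIParams], path) -> None:
    rows = [
        {"name": name, **{k: getattr(p, k) for k in _TI_FIELDS}}
        for name, p in materials.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_dist_spec(path) -> DistSpec:
    return DistSpec.from_dict(json.loads(Path(path).read_text()))


def write_dist_spec(spec: DistSpec, path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2) + "\n")


def read_intensity_grid(path) -> IntensityGrid:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["X2", "intensity"], path)
    if "X1" in df.columns:
        coords = df[["X1", "X2"]].to_numpy(float)
    else:
        coords = df["X2"].to_numpy(float)
    return IntensityGrid(coords=coords, intensity=df["intensity"].to_numpy(float))


def write_intensity_grid(grid: IntensityGrid, path) -> None:
    c = np.asarray(grid.coords)
    if c.ndim == 2:
        df = pd.DataFrame({"X1": c[:, 0], "X2": c[:, 1], "intensity": grid.intensity})
    else:
        df = pd.DataFrame({"X2": c, "intensity": grid.intensity})
    df.to_csv(path, index=False, float_format="%.17g")


def read_fd_curve(path, gauge_length=None, area=None) -> FDCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["displacement", "force"], path)
    gl = gauge_length if gauge_length is not None else float(df["gauge_length"].iloc[0])
    ar = area if area is not None else float(df["area"].iloc[0])
    return FDCurve(
        displacements=df["displacement"].to_numpy(float),
        forces=df["force"].to_numpy(float),
        gauge_length=gl,
        area=ar,
    )


def write_fd_curve(curve: FDCurve, path) -> None:
    pd.DataFrame(
        {
            "displacement": curve.displacements,
            "force": curve.forces,
            "gauge_length": curve.gauge_length,
            "area": curve.area,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_chain_geometry(path) -> ChainGeometry:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["t", "length", "area"], path)
    fid_cols = [c for c in df.columns if c == "fiducial"]
    if fid_cols:
        fid = df["fiducial"].dropna().to_numpy(float)
    else:
        total = float(df["length"].sum())
        fid = np.linspace(0.0, total, 12)[1:-1]
    return ChainGeometry(
        layer_lengths=df["length"].to_numpy(float),
        layer_areas=df["area"].to_numpy(float),
        fiducials=fid,
    )


def write_chain_geometry(geom: ChainGeometry, path) -> None:
    n = geom.n_layers
    fid = list(geom.fiducials) + [np.nan] * max(0, n - len(geom.fiducials))
    df = pd.DataFrame(
        {
            "t": np.arange(1, n + 1),
            "length": geom.layer_lengths,
            "area": geom.layer_areas,
            "fiducial": fid[:n] if len(fid) >= n else fid,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_strain_profile(path) -> StrainProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["fiducial", "step", "strain_norm"], path)
    fid = np.unique(df["fiducial"].to_numpy(float))
    steps = np.unique(df["step"].to_numpy(float))
    mat = (
        df.pivot(index="fiducial", columns="step", values="strain_norm")
        .loc[fid, steps]
        .to_numpy(float)
    )
    return StrainProfile(fiducials=fid, load_steps=steps, strains=mat)


def write_strain_profile(profile: StrainProfile, path) -> None:
    rows = []
    for i, fid in enumerate(profile.fiducials):
        for j, s in enumerate(profile.load_steps):
            rows.append(
                {"fiducial": fid, "step": s, "strain_norm": profile.strains[i, j]}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_stack(stack: GradedStack, path) -> None:
    stack.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_stack_params(path, K_col: str = "K") -> list[TIParams]:
    """Read the per-layer TI parameters back from a stack CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _TI_FIELDS, path)
    return [
        TIParams(**{k: float(r[k]) for k in _TI_FIELDS}) for _, r in df.iterrows()
    ]
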