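"""CSV/JSON/YAML interchange for profiles, reports and survival data.

No domain standard exists for depth-dose/LET tables, so the package uses
tidy CSV with unit-bearing headers: one row per (depth, component) for
field profiles, one row per (dose, condition) for survival data.  Reports
are written as tidy CSV plus a JSON summary, and every run can drop a
manifest (config + package version + seed) for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import load_tissue
from .field import BeamComponent, DoseReport, FieldProfile
from .lq import TissueParams
from .survival import SurvivalDataset

__all__ = [
    "read_field_profile",
    "write_field_profile",
    "read_survival_csv",
    "write_survival_csv",
    "write_report",
    "write_manifest",
    "resolve_tissue",
]

_PROFILE_REQUIRED = ["depth_mm", "component", "dose_Gy", "let_d_keV_um"]
_PROFILE_OPTIONAL = {
    "zstar_Gy": "z_star",
    "alpha_z_Gy": "alpha_z",
    "beta_z_Gy2": "beta_z",
    "d1_Gy": "d1",
}


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def read_field_profile(path) -> FieldProfile:
    """Read a tidy profile CSV (depth_mm, component, z, dose_Gy, let_d_keV_um,
    optional zstar_Gy / alpha_z_Gy / beta_z_Gy2 / d1_Gy)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _PROFILE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)} "
            "(headers must carry units, e.g. dose_Gy)"
        )
    depth = np.array(sorted(df["depth_mm"].unique()), dtype=float)
    if len(depth) < 2 or not np.all(np.diff(depth) > 0):
        raise SchemaError(f"{path}: depth grid must be strictly increasing")
    comps = []
    for name, g in df.groupby("component", sort=False):
        g = g.sort_values("depth_mm")
        if len(g) != len(depth) or not np.allclose(g["depth_mm"].to_numpy(), depth):
            raise SchemaError(
                f"{path}: component {name!r} does not cover the full depth grid"
            )
        kwargs = {}
        for col, attr in _PROFILE_OPTIONAL.items():
            if col in g.columns and g[col].notna().all():
                kwargs[attr] = g[col].to_numpy(dtype=float)
        comps.append(
            BeamComponent(
                name=str(name),
                dose=g["dose_Gy"].to_numpy(dtype=float),
                let_d=g["let_d_keV_um"].to_numpy(dtype=float),
                z=int(g["z"].iloc[0]) if "z" in g.columns else 2,
                **kwargs,
            )
        )
    return FieldProfile(depth=depth, components=comps, metadata={"source": str(path)})


def write_field_profile(profile: FieldProfile, path) -> None:
    rows = []
    for c in profile.components:
        for i, z_mm in enumerate(profile.depth):
            row = {
                "depth_mm": z_mm,
                "component": c.name,
                "z": c.z,
                "dose_Gy": c.dose[i],
                "let_d_keV_um": c.let_d[i],
            }
            for col, attr in _PROFILE_OPTIONAL.items():
                v = getattr(c, attr)
                if v is not None:
                    row[col] = v[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survival_csv(path) -> SurvivalDataset:
    """Read survival records (dose_Gy, sf, optional sd, n, radiation, condition)."""
    df = pd.read_csv(path, comment="#")
    for col in ("dose_Gy", "sf"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return SurvivalDataset(
        dose=df["dose_Gy"].to_numpy(dtype=float),
        surviving_fraction=df["sf"].to_numpy(dtype=float),
        sd=df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None,
        n_replicates=df["n"].to_numpy(dtype=float) if "n" in df.columns else None,
        radiation_label=str(df["radiation"].iloc[0]) if "radiation" in df.columns else "",
        condition_label=str(df["condition"].iloc[0]) if "condition" in df.columns else "",
    )


def write_survival_csv(data: SurvivalDataset, path) -> None:
    df = pd.DataFrame(
        {
            "dose_Gy": data.dose,
            "sf": data.surviving_fraction,
            "sd": data.sd if data.sd is not None else np.nan,
            "n": data.n_replicates if data.n_replicates is not None else np.nan,
            "radiation": data.radiation_label,
            "condition": data.condition_label,
        }
    )
    df.to_csv(path, index=False)


def write_report(report: DoseReport, out_dir) -> dict:
    """Write a forward report as tidy CSV plus a JSON summary; returns the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = {
        "depth_mm": report.depth,
        "dose_Gy": report.dose,
        "let_d_keV_um": report.let_d,
    }
    for name, c in report.curves.items():
        cols[f"rbe_{name}"] = c.rbe
        cols[f"d_rbe_{name}_GyRBE"] = c.d_rbe
    pd.DataFrame(cols).to_csv(out / "report.csv", index=False)
    summary = {
        "models": list(report.curves),
        "depth_range_mm": [float(report.depth[0]), float(report.depth[-1])],
        "max_dose_Gy": float(np.max(report.dose)),
        "max_d_rbe_GyRBE": {
            name: float(np.nanmax(c.d_rbe)) for name, c in report.curves.items()
        },
        "metadata": report.metadata,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def write_manifest(out_dir, config: dict, seed: int | None = None) -> Path:
    """Drop a manifest (config + package version + seed) alongside outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"herbe_version": __version__, "seed": seed, "config": config}
    p = out / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return p


def resolve_tissue(ref: str) -> TissueParams:
    """Resolve ``name`` (packaged tissue) or ``file.yaml#key`` to parameters."""
    if "#" in ref:
        path, key = ref.rsplit("#", 1)
        with open(path) as fh:
            table = yaml.safe_load(fh)
        if key not in table:
            raise SchemaError(f"{path}: no tissue {key!r}; available: {sorted(table)}")
        rec = table[key]
        return TissueParams(
            alpha_x=float(rec["alpha_x"]),
            beta_x=float(rec["beta_x"]),
            d_t=float(rec["d_t"]) if rec.get("d_t") is not None else None,
            label=str(rec.get("label", key)),
        )
    return load_tissue(ref)
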