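"""Depth-resolved biological dose for mixed helium fields.

A clinical helium field at a given depth is a mixture: Z=2 primaries plus
secondary fragments, and Z=1 secondary fragments, each carrying its own dose
and dose-averaged LET (and, per model, its own microdosimetric/intrinsic
inputs).  The forward calculation evaluates a model LQ pair per component,
combines them with the standard dose-weighted mixed-field rule

    alpha_mix = sum(d_i alpha_i) / sum(d_i)
    sqrt(beta_mix) = sum(d_i sqrt(beta_i)) / sum(d_i)

(Zaider-Rossi form) and then applies the closed-form isoeffect RBE at the
local total dose.  On top of that sit spread-out-Bragg-peak (SOBP) weight
optimization, percent-difference model comparison, DVH statistics and the
equivalent uniform dose of the target.

Geometry is 1-D depth in water (mm).  Depths measured in PMMA convert to
water-equivalent depth with a fixed multiplicative factor of 1.165.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .lq import LQPair, TissueParams, eud, rbe_closed_form
from .models import (
    DDMCoefficients,
    LEMTable,
    MKMParams,
    ZStarTable,
    model_lq,
    rescale_let,
    single_traversal_dose,
)

__all__ = [
    "BeamComponent",
    "FieldProfile",
    "ModelCurve",
    "DoseReport",
    "DVHStats",
    "SOBPResult",
    "PMMA_TO_WED",
    "pmma_to_wed",
    "mix_lq",
    "forward_drbe",
    "percent_delta",
    "combine_profiles",
    "optimize_sobp",
    "dvh_stats",
    "target_eud",
]

#: PMMA depth -> water-equivalent depth multiplicative factor.
PMMA_TO_WED = 1.165


def pmma_to_wed(depth_pmma):
    """Convert PMMA depth to water-equivalent depth (same units in/out)."""
    d = np.asarray(depth_pmma, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    out = d * PMMA_TO_WED
    return float(out) if out.ndim == 0 else out


@dataclass
class BeamComponent:
    """One charge component of a field: dose and LET_d per depth.

    ``z`` is the particle charge (2 for helium primaries and Z=2 fragments,
    1 for proton-like fragments).  Optional per-depth model inputs
    (``z_star`` for MKM; ``alpha_z``/``beta_z``/``d1`` for LEM) override
    table lookups in :func:`forward_drbe`.
    """

    name: str
    dose: np.ndarray  # Gy
    let_d: np.ndarray  # keV/um
    z: int = 2
    z_star: np.ndarray | None = None  # Gy
    alpha_z: np.ndarray | None = None  # Gy^-1
    beta_z: np.ndarray | None = None  # Gy^-2
    d1: np.ndarray | None = None  # Gy

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.let_d = np.asarray(self.let_d, dtype=float)
        if self.dose.shape != self.let_d.shape:
            raise ValueError(f"component {self.name}: dose/let_d length mismatch")
        if np.any(self.dose < 0):
            raise ValueError(f"component {self.name}: negative dose")
        for attr in ("z_star", "alpha_z", "beta_z", "d1"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.dose.shape:
                    raise ValueError(f"component {self.name}: {attr} length mismatch")
                setattr(self, attr, v)


@dataclass
class FieldProfile:
    """Depth-gridded mixed field: strictly increasing depth (mm) + components."""

    depth: np.ndarray  # mm
    components: list[BeamComponent]
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or not np.all(np.diff(self.depth) > 0):
            raise ValueError("depth grid must be 1-D and strictly increasing")
        for c in self.components:
            if c.dose.shape != self.depth.shape:
                raise ValueError(
                    f"component {c.name}: arrays do not match depth grid length"
                )

    @property
    def total_dose(self) -> np.ndarray:
        """Total physical dose per depth, summed over components (Gy)."""
        return np.sum([c.dose for c in self.components], axis=0)

    def max_z2_dose(self) -> float:
        z2 = [c.dose for c in self.components if c.z == 2]
        return float(np.max(np.sum(z2, axis=0))) if z2 else 0.0

    def dose_averaged_let(self) -> np.ndarray:
        """Dose-weighted mean LET_d across components (nan where dose = 0)."""
        tot = self.total_dose
        num = np.sum([c.dose * c.let_d for c in self.components], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, num / np.where(tot > 0, tot, 1.0), np.nan)


@dataclass
class ModelCurve:
    """Forward-calculated curves for one RBE model on a profile's grid."""

    model: str
    rbe: np.ndarray
    d_rbe: np.ndarray  # Gy (RBE)
    alpha_mix: np.ndarray  # Gy^-1, mixed-field macroscopic alpha
    beta_mix: np.ndarray  # Gy^-2


@dataclass
class DoseReport:
    """Per-depth physical and biological dose with per-model curves.

    ``let_d`` is the dose-averaged LET, masked (NaN) at depths where the
    total dose falls below 5% of the maximum Z=2 dose, mirroring the
    LET_d scoring threshold used when fields are scored by Monte Carlo.
    """

    depth: np.ndarray
    dose: np.ndarray
    let_d: np.ndarray
    let_mask: np.ndarray  # True where LET_d is reportable
    curves: dict[str, ModelCurve]
    metadata: dict = dc_field(default_factory=dict)

    def percent_delta(self, model_a: str, model_b: str) -> np.ndarray:
        """Pairwise %Delta of D_RBE between two models, per depth."""
        return percent_delta(self.curves[model_a].d_rbe, self.curves[model_b].d_rbe)


def mix_lq(doses: Sequence[float], lqs: Sequence[LQPair]) -> LQPair:
    """Dose-weighted mixed-field LQ combination (Zaider-Rossi form).

    ``alpha`` mixes linearly in dose; ``sqrt(beta)`` mixes linearly in dose.
    A single component is returned unchanged.
    """
    d = np.asarray(doses, dtype=float)
    if len(d) != len(lqs):
        raise ValueError("doses and lqs must have equal length")
    if np.any(d < 0):
        raise ValueError("component doses must be >= 0")
    tot = d.sum()
    if tot <= 0:
        raise ValueError("mixed field needs at least one component with dose > 0")
    alphas = np.array([q.alpha for q in lqs])
    sqrt_betas = np.sqrt([q.beta for q in lqs])
    return LQPair(
        alpha=float(np.dot(d, alphas) / tot),
        beta=float((np.dot(d, sqrt_betas) / tot) ** 2),
    )


def percent_delta(series_a, series_b) -> np.ndarray:
    """Percent difference ``100*(a-b)/b`` per point; NaN where ``b == 0``."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share the same grid")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(b != 0, 100.0 * (a - b) / np.where(b != 0, b, 1.0), np.nan)
    return out


def _component_lq(
    comp: BeamComponent,
    i: int,
    model: str,
    tissue: TissueParams,
    coeffs: DDMCoefficients,
    zstar_table: ZStarTable | None,
    lem_table: LEMTable | None,
    mkm_params: MKMParams,
    mode: str,
) -> LQPair:
    """Model LQ pair of one component at depth index ``i``."""
    let = float(comp.let_d[i])
    if model == "ddm":
        return model_lq(
            "ddm", tissue, l_star=rescale_let(let, coeffs, mode), coeffs=coeffs
        )
    if model == "mkm":
        if comp.z_star is not None:
            zs = float(comp.z_star[i])
        elif zstar_table is not None:
            zs = float(zstar_table(let))
        else:
            raise ValueError(
                f"mkm input missing for component {comp.name!r} at depth index {i}: "
                "provide per-depth z_star or a ZStarTable"
            )
        return model_lq("mkm", tissue, z_star=zs)
    if model == "lem":
        if comp.alpha_z is not None:
            az = float(comp.alpha_z[i])
        elif lem_table is not None:
            az = float(lem_table.alpha_z_at(let))
        else:
            raise ValueError(
                f"lem input missing for component {comp.name!r} at depth index {i}: "
                "provide per-depth alpha_z or a LEMTable"
            )
        if comp.beta_z is not None:
            bz = float(comp.beta_z[i])
        elif lem_table is not None:
            bz = float(lem_table.beta_z_at(let, tissue))
        else:  # pragma: no cover - guarded above
            raise ValueError("lem beta_z missing")
        if comp.d1 is not None:
            d1 = float(comp.d1[i])
        else:
            d1 = single_traversal_dose(let, mkm_params)
        return model_lq("lem", tissue, alpha_z=az, beta_z=bz, d1=d1)
    raise ValueError(f"unknown model {model!r}")


def forward_drbe(
    profile: FieldProfile,
    model: Literal["ddm", "mkm", "lem"],
    tissue: TissueParams,
    *,
    coeffs: DDMCoefficients = DDMCoefficients(),
    zstar_table: ZStarTable | None = None,
    lem_table: LEMTable | None = None,
    mkm_params: MKMParams = MKMParams(),
    mode: Literal["track_segment", "clinical"] = "track_segment",
) -> DoseReport:
    """Forward biological-dose calculation of one model over a profile.

    Per depth: model LQ per component, dose-weighted mixing, closed-form RBE
    at the local total dose.  Depths with zero total dose get RBE = NaN and
    D_RBE = 0.
    """
    n = len(profile.depth)
    total = profile.total_dose
    rbe = np.full(n, np.nan)
    alpha_mix = np.full(n, np.nan)
    beta_mix = np.full(n, np.nan)
    for i in range(n):
        live = [c for c in profile.components if c.dose[i] > 0]
        if not live:
            continue
        lqs = [
            _component_lq(
                c, i, model, tissue, coeffs, zstar_table, lem_table, mkm_params, mode
            )
            for c in live
        ]
        mixed = mix_lq([c.dose[i] for c in live], lqs)
        alpha_mix[i] = mixed.alpha
        beta_mix[i] = mixed.beta
        pt = rbe_closed_form(
            tissue,
            float(total[i]),
            mixed.alpha / tissue.alpha_x,
            mixed.beta / tissue.beta_x,
        )
        rbe[i] = pt.rbe
    d_rbe = np.where(np.isnan(rbe), 0.0, rbe * total)
    mask = total >= 0.05 * profile.max_z2_dose()
    let_d = np.where(mask, profile.dose_averaged_let(), np.nan)
    curve = ModelCurve(model=model, rbe=rbe, d_rbe=d_rbe,
                       alpha_mix=alpha_mix, beta_mix=beta_mix)
    return DoseReport(
        depth=profile.depth,
        dose=total,
        let_d=let_d,
        let_mask=mask,
        curves={model: curve},
        metadata=dict(profile.metadata),
    )


def combine_profiles(
    kernels: Sequence[FieldProfile], weights: Sequence[float]
) -> FieldProfile:
    """Weighted superposition of kernels sharing one depth grid.

    Component doses add; LET_d and optional model inputs combine
    dose-weighted (the mixed-field average appropriate for all quantities
    that later mix linearly in dose).
    """
    if len(kernels) != len(weights):
        raise ValueError("one weight per kernel required")
    depth = kernels[0].depth
    for k in kernels[1:]:
        if k.depth.shape != depth.shape or not np.allclose(k.depth, depth):
            raise ValueError("all kernels must share the same depth grid")
    names = []
    for k in kernels:
        for c in k.components:
            if c.name not in names:
                names.append(c.name)
    out = []
    for name in names:
        parts = [
            (w, c)
            for k, w in zip(kernels, weights)
            for c in k.components
            if c.name == name
        ]
        dose = np.sum([w * c.dose for w, c in parts], axis=0)
        safe = np.where(dose > 0, dose, 1.0)

        def wavg(attr):
            if any(getattr(c, attr) is None for _, c in parts):
                return None
            num = np.sum([w * c.dose * getattr(c, attr) for w, c in parts], axis=0)
            return np.where(dose > 0, num / safe, 0.0)

        out.append(
            BeamComponent(
                name=name,
                dose=dose,
                let_d=wavg("let_d"),
                z=parts[0][1].z,
                z_star=wavg("z_star"),
                alpha_z=wavg("alpha_z"),
                beta_z=wavg("beta_z"),
                d1=wavg("d1"),
            )
        )
    return FieldProfile(depth=depth, components=out,
                        metadata={"combined_from": len(kernels)})


@dataclass
class SOBPResult:
    """Outcome of SOBP weight optimization."""

    weights: np.ndarray
    profile: FieldProfile  # weighted superposition
    report: DoseReport | None  # biological mode only
    iterations: int
    converged: bool
    target_slice: slice


def optimize_sobp(
    kernels: Sequence[FieldProfile],
    prescription: float,
    target_interval: tuple[float, float],
    model: Literal["ddm", "mkm", "lem"] | None = None,
    tissue: TissueParams | None = None,
    *,
    mode: Literal["physical", "biological"] = "physical",
    tol: float = 1e-4,
    max_iter: int = 200,
    **forward_kwargs,
) -> SOBPResult:
    """Optimize pristine-kernel weights for a flat SOBP.

    ``physical`` mode solves a bounded (nonnegative) least-squares problem
    for a flat physical dose equal to ``prescription`` over the target
    interval.  ``biological`` mode starts from that solution and iterates a
    fixed point on the kernel Bragg-peak positions: with ``RBE(z)`` frozen
    from the current field, re-solve the bounded least-squares system for
    physical peak doses ``prescription / RBE(z_peak)``, until the biological
    dose at every kernel peak inside the target matches the prescription to
    ``tol`` (relative).  Because RBE depends only weakly on the weight
    vector this Newton-type update typically converges in < 10 iterations.
    """
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    lo, hi = target_interval
    depth = kernels[0].depth
    peaks = np.array([k.depth[np.argmax(k.total_dose)] for k in kernels])
    spacing = np.max(np.diff(np.sort(peaks))) if len(peaks) > 1 else np.inf
    uncovered = []
    if peaks.min() > lo + max(spacing, 1.0):
        uncovered.append(f"[{lo:g}, {peaks.min():g}) mm")
    if peaks.max() < hi - max(spacing, 1.0):
        uncovered.append(f"({peaks.max():g}, {hi:g}] mm")
    if uncovered:
        raise ValueError(
            "kernel Bragg peaks do not span the target interval; uncovered: "
            + ", ".join(uncovered)
        )
    sel = (depth >= lo) & (depth <= hi)
    if not np.any(sel):
        raise ValueError("target interval contains no grid points")
    idx = np.where(sel)[0]
    target_slice = slice(idx[0], idx[-1] + 1)

    a_mat = np.stack([k.total_dose[sel] for k in kernels], axis=1)
    res = lsq_linear(a_mat, np.full(sel.sum(), prescription), bounds=(0, np.inf))
    weights = res.x

    if mode == "physical":
        return SOBPResult(
            weights=weights,
            profile=combine_profiles(kernels, weights),
            report=None,
            iterations=0,
            converged=res.success,
            target_slice=target_slice,
        )

    if model is None or tissue is None:
        raise ValueError("biological mode needs a model and a tissue")
    peak_idx = np.array([int(np.argmax(k.total_dose)) for k in kernels])
    in_target = sel[peak_idx]
    a_peaks = np.stack([k.total_dose[peak_idx] for k in kernels], axis=1)
    converged = False
    it = 0
    report = None
    for it in range(1, max_iter + 1):
        profile = combine_profiles(kernels, weights)
        report = forward_drbe(profile, model, tissue, **forward_kwargs)
        d_rbe_pk = report.curves[model].d_rbe[peak_idx]
        with np.errstate(divide="ignore"):
            ratio = np.where(d_rbe_pk > 0, prescription / d_rbe_pk, 1.0)
        err = np.max(np.abs(ratio[in_target] - 1.0)) if in_target.any() else 0.0
        if err < tol:
            converged = True
            break
        rbe_pk = report.curves[model].rbe[peak_idx]
        weights = lsq_linear(
            a_peaks, prescription / rbe_pk, bounds=(0, np.inf)
        ).x
    if not converged:
        warnings.warn(
            f"SOBP biological optimization did not reach tol={tol} in "
            f"{max_iter} iterations",
            UserWarning,
        )
    return SOBPResult(
        weights=weights,
        profile=combine_profiles(kernels, weights),
        report=report,
        iterations=it,
        converged=converged,
        target_slice=target_slice,
    )


@dataclass
class DVHStats:
    """Cumulative DVH summary.

    ``d(x)`` follows the ">= threshold" convention: the largest sample dose
    received by at least x% of the volume.  ``I_5`` is the inhomogeneity
    coefficient ``(D_5% - D_95%) / prescription``.
    """

    d50: float
    d5: float
    d95: float
    i5: float | None
    dose_sorted: np.ndarray  # descending
    cum_volume: np.ndarray  # increasing fraction in (0, 1]

    def d(self, x: float) -> float:
        """Dose received by at least ``x`` % of the volume."""
        f = x / 100.0
        k = int(np.searchsorted(self.cum_volume, f - 1e-12))
        k = min(k, len(self.dose_sorted) - 1)
        return float(self.dose_sorted[k])


def dvh_stats(
    doses, volumes=None, prescription: float | None = None
) -> DVHStats:
    """DVH statistics D_50%, D_5%, D_95% and I_5% of a dose sample.

    ``volumes`` are optional relative volume weights (default: equal voxels).
    ``D_x%`` is the largest dose such that the volume fraction receiving at
    least that dose is >= x/100, evaluated on the sorted sample.
    """
    d = np.asarray(doses, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty dose sample")
    if volumes is None:
        w = np.full(d.size, 1.0 / d.size)
    else:
        w = np.asarray(volumes, dtype=float).ravel()
        if w.shape != d.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("volumes must be nonnegative weights matching doses")
        w = w / w.sum()
    order = np.argsort(-d, kind="stable")
    ds = d[order]
    cum = np.cumsum(w[order])
    cum[-1] = 1.0  # guard rounding
    stats = DVHStats(
        d50=np.nan, d5=np.nan, d95=np.nan, i5=None, dose_sorted=ds, cum_volume=cum
    )
    stats.d50 = stats.d(50.0)
    stats.d5 = stats.d(5.0)
    stats.d95 = stats.d(95.0)
    if prescription is not None:
        if prescription <= 0:
            raise ValueError("prescription must be > 0")
        stats.i5 = (stats.d5 - stats.d95) / prescription
    return stats


def target_eud(
    report: DoseReport, tissue: TissueParams, model: str | None = None,
    target: tuple[float, float] | slice | None = None,
) -> float:
    """Equivalent uniform dose of the target region of a forward report.

    Per-voxel survival is computed from the mixed-field LQ pair at the local
    physical dose, averaged over the target, and converted with the EUD
    closed form.  ``target`` selects depths (mm interval or slice); default
    is the whole grid.
    """
    if model is None:
        if len(report.curves) != 1:
            raise ValueError("report holds several models; name one")
        model = next(iter(report.curves))
    curve = report.curves[model]
    if target is None:
        sel = np.ones(len(report.depth), dtype=bool)
    elif isinstance(target, slice):
        sel = np.zeros(len(report.depth), dtype=bool)
        sel[target] = True
    else:
        lo, hi = target
        sel = (report.depth >= lo) & (report.depth <= hi)
    if not np.any(sel):
        raise ValueError("target selects no depths")
    dose = report.dose[sel]
    a = curve.alpha_mix[sel]
    b = curve.beta_mix[sel]
    effect = np.where(dose > 0, a * dose + b * dose**2, 0.0)
    mean_survival = float(np.mean(np.exp(-effect)))
    return eud(tissue, mean_survival)
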