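"""Synthetic helium beams, model-input fixtures and simulated plates.

Deterministic, seedable stand-ins for the two upstream data sources of the
RBE pipeline: Monte-Carlo-scored depth profiles (dose and dose-averaged LET
per field component) and wet-lab clonogenic colony counts.

The pristine Bragg curve is an explicit analytic parameterization — a gently
rising plateau, a Gaussian-broadened peak at the nominal range, a sigmoid
distal edge and an optional exponential Z=1 fragment tail — not a transport
calculation.  Its LET_d rise toward the peak follows a saturating
residual-range power law whose two shape parameters can be solved from
stated (depth, LET) anchor points, so that published anchor conditions
(e.g. a 56.66 MeV/u beam with its Bragg peak at 25.9 mm showing ~6 keV/um
at 6 mm and ~15 keV/um at 12 mm) are reproduced by construction.

Colony counts are Poisson around ``cells * plating_efficiency * S_LQ(D)``;
the error model is a declared stand-in (real assays report only mean ± SD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .field import BeamComponent, FieldProfile
from .lq import LQPair, TissueParams, lq_survival
from .models import LEMTable, ZStarTable, lem_beta_z
from .survival import SurvivalDataset

__all__ = [
    "BeamSpec",
    "PlateSimSpec",
    "pristine_profile",
    "kernel_library",
    "zstar_fixture",
    "lem_fixture",
    "simulate_plate",
]

#: smoothing length (mm) of the residual-range LET law, keeps LET finite at the peak
_LET_SMOOTHING_MM = 2.0


@dataclass(frozen=True)
class BeamSpec:
    """Parameters of one synthetic pristine helium beam.

    ``range_w`` is the Bragg-peak depth in water (mm); ``peak_width`` the
    FWHM of the Gaussian peak (mm); ``fragment_tail_fraction`` the entrance
    dose fraction carried by the Z=1 fragment component (0 disables it).
    ``entrance_let``/``peak_let`` anchor the LET_d curve at z=0 and at the
    peak; ``let_exponent``/``let_scale`` shape its rise (see
    :meth:`from_let_anchors`).
    """

    energy: float = 56.66  # MeV/u, label only
    range_w: float = 25.9  # mm
    peak_width: float = 2.5  # mm FWHM
    fragment_tail_fraction: float = 0.0
    entrance_let: float = 4.0  # keV/um
    peak_let: float = 40.0  # keV/um
    peak_plateau_ratio: float = 2.0
    plateau_slope: float = 0.15  # relative plateau rise over the full range
    let_exponent: float = 3.0
    let_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.range_w <= 0:
            raise ValueError("range_w must be > 0")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")
        if not 0 <= self.fragment_tail_fraction < 0.3:
            raise ValueError("fragment_tail_fraction must be in [0, 0.3)")
        if self.peak_let <= self.entrance_let:
            raise ValueError("peak_let must exceed entrance_let")
        if self.peak_plateau_ratio <= 1:
            raise ValueError("peak_plateau_ratio must be > 1")

    # -- LET_d(z) ----------------------------------------------------------
    def let_d(self, z: np.ndarray) -> np.ndarray:
        """Dose-averaged LET (keV/um) at depth ``z`` mm.

        Rises monotonically from ``entrance_let`` and saturates at
        ``peak_let`` approaching the peak; constant beyond it.
        """
        z = np.asarray(z, dtype=float)
        s = _LET_SMOOTHING_MM
        zc = np.minimum(z, self.range_w)
        f = ((self.range_w + s) / (self.range_w - zc + s)) ** self.let_exponent - 1.0
        return self.peak_let - (self.peak_let - self.entrance_let) * np.exp(
            -self.let_scale * f
        )

    @classmethod
    def from_let_anchors(
        cls,
        anchors: Sequence[tuple[float, float]],
        **kwargs,
    ) -> "BeamSpec":
        """Build a spec whose LET curve passes through (depth, LET) anchors.

        Solves ``let_exponent`` and ``let_scale`` by least squares so that
        ``let_d(depth) = let`` at every anchor; other fields come from
        ``kwargs``.  Two anchors determine the two parameters exactly.
        """
        base = cls(**kwargs)
        zs = np.array([a[0] for a in anchors], dtype=float)
        ls = np.array([a[1] for a in anchors], dtype=float)
        if np.any(zs >= base.range_w):
            raise ValueError("anchors must lie before the Bragg peak")
        if np.any((ls <= base.entrance_let) | (ls >= base.peak_let)):
            raise ValueError("anchor LETs must lie between entrance and peak LET")

        def resid(p):
            spec = replace(base, let_exponent=p[0], let_scale=math.exp(p[1]))
            return spec.let_d(zs) - ls

        sol = least_squares(resid, x0=[4.0, math.log(0.03)], method="lm")
        spec = replace(base, let_exponent=float(sol.x[0]),
                       let_scale=float(math.exp(sol.x[1])))
        if not np.allclose(spec.let_d(zs), ls, rtol=5e-3):
            raise ValueError("could not satisfy the requested LET anchors")
        return spec

    @classmethod
    def experiment_a(cls, **kwargs) -> "BeamSpec":
        """The monoenergetic reference beam: 56.66 MeV/u, peak at 25.9 mm,
        LET_d ~6 keV/um at 6 mm and ~15 keV/um at 12 mm depth."""
        kwargs.setdefault("energy", 56.66)
        kwargs.setdefault("range_w", 25.9)
        return cls.from_let_anchors([(6.0, 6.0), (12.0, 15.0)], **kwargs)


def _he_dose(spec: BeamSpec, z: np.ndarray) -> np.ndarray:
    """Analytic helium depth dose: plateau * distal sigmoid + Gaussian peak."""
    sigma = spec.peak_width / 2.3548  # FWHM -> sigma
    delta = 1.5 * sigma
    w_edge = 0.35 * sigma
    plateau = 1.0 + spec.plateau_slope * np.minimum(z, spec.range_w) / spec.range_w
    edge = 1.0 / (1.0 + np.exp((z - (spec.range_w + delta)) / w_edge))
    base = plateau * edge
    entrance = float(base[0]) if np.ndim(z) else base
    peak_amp = spec.peak_plateau_ratio * entrance - (
        (1.0 + spec.plateau_slope) / (1.0 + math.exp(-delta / w_edge))
    )
    gauss = peak_amp * np.exp(-((z - spec.range_w) ** 2) / (2.0 * sigma**2))
    return base + gauss


def pristine_profile(
    spec: BeamSpec, step: float = 0.1, z_max: float | None = None
) -> FieldProfile:
    """Depth-gridded pristine beam with He (Z=2) and optional Z=1 tail.

    Entrance dose is 1 Gy per unit weight; the dose maximum sits within one
    grid step of ``spec.range_w`` and the peak-to-plateau ratio matches the
    spec (default ~2, typical for helium beams).
    """
    if step <= 0:
        raise ValueError("grid step must be > 0")
    if z_max is None:
        z_max = spec.range_w + max(8.0 * spec.peak_width, 0.35 * spec.range_w)
    z = np.arange(0.0, z_max + step / 2, step)
    he = _he_dose(spec, z)
    comps = [BeamComponent(name="He_primary_and_Z2", dose=he,
                           let_d=spec.let_d(z), z=2)]
    if spec.fragment_tail_fraction > 0:
        buildup = 0.5 + 0.5 * np.minimum(z / spec.range_w, 1.0)
        decay = np.exp(-np.maximum(z - spec.range_w, 0.0) / (0.3 * spec.range_w))
        z1 = spec.fragment_tail_fraction * he[0] * buildup * decay
        comps.append(
            BeamComponent(name="Z1_fragments", dose=z1,
                          let_d=np.full_like(z, 2.0), z=1)
        )
    return FieldProfile(
        depth=z,
        components=comps,
        metadata={"energy_MeV_u": spec.energy, "range_mm": spec.range_w},
    )


def kernel_library(
    range_min: float,
    range_max: float,
    spacing: float = 2.0,
    step: float = 0.1,
    **spec_kwargs,
) -> list[FieldProfile]:
    """Pristine kernels with Bragg peaks evenly spaced over a range span.

    Peaks sit at ``range_min, range_min+spacing, ..., range_max`` (default
    2 mm separation between consecutive energy slices); all kernels share
    one depth grid.  Deeper kernels are slightly broader, mimicking range
    straggling.
    """
    if range_max <= range_min:
        raise ValueError("range_max must exceed range_min")
    n = int(round((range_max - range_min) / spacing)) + 1
    if n < 2:
        raise ValueError("need at least 2 kernels; widen the span")
    peaks = range_min + spacing * np.arange(n)
    base_width = spec_kwargs.pop("peak_width", 2.5)
    z_max = range_max + max(8.0 * base_width * 1.5, 0.35 * range_max)
    kernels = []
    for r in peaks:
        spec = BeamSpec(
            range_w=float(r),
            peak_width=base_width * (1.0 + 0.01 * (r - range_min)),
            energy=56.66 * (float(r) / 25.9) ** (1.0 / 1.8),
            **spec_kwargs,
        )
        kernels.append(pristine_profile(spec, step=step, z_max=z_max))
    return kernels


def zstar_fixture(
    let_grid, z_sat: float = 12.0, let_scale: float = 35.0
) -> ZStarTable:
    """Smooth plausible ``z*_1D`` table: rises from 0 and saturates.

    ``z* = z_sat * tanh(LET/let_scale)`` — zero at zero LET, monotone, and
    flattening at high LET, emulating the shape the overkill (saturation)
    correction imposes.  A machinery fixture, not a microdosimetric result.
    """
    let = np.asarray(let_grid, dtype=float)
    return ZStarTable(abscissa=let, z_star_1d=z_sat * np.tanh(let / let_scale))


def lem_fixture(let_grid, tissue: TissueParams, let_scale: float = 30.0) -> LEMTable:
    """Smooth plausible intrinsic LEM table for machinery tests.

    ``alpha_z`` rises from ``alpha_x`` toward the tissue's maximum slope
    ``s_max`` with LET; ``beta_z`` follows the ``(s_max - alpha_z)/(2 D_t)``
    approximation (so it decreases with LET and hits zero at saturation).
    Explicitly not claimed to reproduce LEM-IV tables.
    """
    if tissue.d_t is None:
        raise ValueError("lem_fixture needs a tissue with D_t")
    let = np.asarray(let_grid, dtype=float)
    s_max = tissue.s_max
    alpha_z = tissue.alpha_x + (s_max - tissue.alpha_x) * (
        1.0 - np.exp(-let / let_scale)
    )
    alpha_z = np.maximum(alpha_z, 1e-6)
    beta_z = lem_beta_z(s_max, alpha_z, tissue.d_t)
    return LEMTable(abscissa=let, alpha_z=alpha_z, beta_z=beta_z, s_max=s_max)


@dataclass(frozen=True)
class PlateSimSpec:
    """Design of a simulated clonogenic well-plate experiment.

    ``true_alpha``/``true_beta`` generate the underlying LQ survival; each
    of ``wells_per_dose`` wells at each dose receives
    ``cells_seeded_per_well`` cells of which a fraction
    ``plating_efficiency`` would form colonies at zero dose.  Default dose
    levels are the standard clonogenic ladder 0.25-3 Gy plus a control.
    """

    true_alpha: float  # Gy^-1
    true_beta: float  # Gy^-2
    dose_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0)
    wells_per_dose: int = 12
    cells_seeded_per_well: int = 300
    plating_efficiency: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wells_per_dose <= 0 or self.cells_seeded_per_well <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.plating_efficiency <= 1:
            raise ValueError("plating_efficiency must be in (0, 1]")
        if any(d < 0 for d in self.dose_levels):
            raise ValueError("doses must be >= 0")


def simulate_plate(spec: PlateSimSpec) -> SurvivalDataset:
    """Simulate colony counts and reduce them to a survival dataset.

    Per well the expected colony count is ``cells * PE * S_LQ(D)``; observed
    counts are Poisson.  The surviving fraction at each dose is the mean
    count over wells divided by ``cells * PE`` (the nominal zero-dose
    expectation), with its standard deviation across wells.  Byte-identical
    for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    lq = LQPair(alpha=spec.true_alpha, beta=spec.true_beta)
    denom = spec.cells_seeded_per_well * spec.plating_efficiency
    doses, sfs, sds, ns = [], [], [], []
    for d in spec.dose_levels:
        expected = denom * lq_survival(lq, d)
        counts = rng.poisson(expected, size=spec.wells_per_dose)
        sf_wells = counts / denom
        doses.append(d)
        sfs.append(float(sf_wells.mean()))
        sds.append(float(sf_wells.std(ddof=1)) if spec.wells_per_dose > 1 else np.nan)
        ns.append(spec.wells_per_dose)
    sfs = np.array(sfs)
    if np.any(sfs > 1.5):  # pathological draw; clip rather than reject
        sfs = np.minimum(sfs, 1.5)
    return SurvivalDataset(
        dose=np.array(doses),
        surviving_fraction=sfs,
        sd=np.array(sds),
        n_replicates=np.array(ns, dtype=float),
        radiation_label="simulated",
        condition_label=f"seed={spec.seed}",
    )
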