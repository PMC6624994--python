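"""RBE model parameterizations for helium-ion beams.

Three published routes from radiation quality to the pair
``(RBE_alpha, R_beta)`` consumed by the closed-form LQ isoeffect RBE:

* **DDM** — a data-driven phenomenological model fit to the in-vitro helium
  literature.  ``RBE_alpha`` depends on a rescaled LET ``L*`` and the tissue
  ratio ``(alpha/beta)_x``; ``R_beta`` is a tissue-independent Gaussian in
  ``L*`` that is set to zero above ~100 keV/um.
* **modified MKM** — the microdosimetric kinetic model with saturation
  correction: ``RBE_alpha = 1 + z*_1D / (alpha/beta)_x`` where ``z*_1D`` is
  the saturation-corrected dose-mean specific energy per event in a domain
  of radius ``R_d`` inside a nucleus of radius ``R_n``; ``R_beta = 1``.
  ``z*_1D`` itself enters as tabulated input (its microdosimetric derivation
  is upstream of this package).
* **LEM (low-dose approximation)** — the local effect model linking intrinsic
  microscopic coefficients ``alpha_z, beta_z`` to macroscopic ones through
  the single-traversal dose ``d_1``:
  ``RBE_alpha = (1 - exp(-alpha_z d_1)) / (alpha_x d_1)`` and
  ``R_beta = (alpha/alpha_z)**2 (beta_z/beta_x)``.  Intrinsic tables are
  user-supplied; ``beta_z`` may be approximated as
  ``(s_max - alpha_z)/(2 D_t)`` clamped at zero.

:func:`model_lq` is the uniform adapter returning the macroscopic LQ pair
``alpha = RBE_alpha * alpha_x``, ``beta = R_beta * beta_x`` for any model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .lq import LQPair, TissueParams

__all__ = [
    "DDMCoefficients",
    "MKMParams",
    "ZStarTable",
    "LEMTable",
    "rescale_let",
    "ddm_rbe_alpha",
    "ddm_r_beta",
    "mkm_rbe_alpha",
    "mkm_r_beta",
    "lem_beta_z",
    "single_traversal_dose",
    "lem_rbe_alpha",
    "lem_r_beta",
    "model_lq",
    "MODEL_NAMES",
]

MODEL_NAMES = ("ddm", "mkm", "lem")

#: Gy * um^3 / keV — converts keV/um deposited over an area in um^2 to Gy
#: at unit density (rho = 1 g/cm^3): 1 keV/um / um^2 = 0.1602 Gy.
KEV_PER_UM3_TO_GY = 0.1602


@dataclass(frozen=True)
class DDMCoefficients:
    """Coefficients of the data-driven phenomenological model.

    Defaults are the published fit values.  ``let_x``/``let_co60`` (the LET
    of the reference photon beam and of Co-60) are needed only for the
    clinical LET-rescaling mode and have no published defaults here.
    """

    k0: float = 8.924e-2  # Gy^-1
    k1: float = 3.368e-1  # um/keV
    k2: float = 2.858e-5  # um^2/keV^2
    b0: float = 2.66
    b1: float = 62.61  # keV/um
    b2: float = 48.12  # keV/um
    let_x: float | None = None  # keV/um, reference-photon LET
    let_co60: float | None = None  # keV/um
    rbeta_cutoff: float = 100.0  # keV/um, R_beta forced to 0 above this


@dataclass(frozen=True)
class MKMParams:
    """Modified-MKM geometry: domain radius ``R_d``, nucleus radius ``R_n`` (um)."""

    r_domain: float = 0.3
    r_nucleus: float = 3.6

    def __post_init__(self) -> None:
        if not 0 < self.r_domain < self.r_nucleus:
            raise ValueError(
                f"need 0 < R_d < R_n, got R_d={self.r_domain}, R_n={self.r_nucleus}"
            )


def _interp_strict(x: np.ndarray, xp: np.ndarray, fp: np.ndarray, what: str) -> np.ndarray:
    """Linear interpolation that refuses to extrapolate biological tables."""
    x = np.asarray(x, dtype=float)
    if np.any(x < xp[0]) or np.any(x > xp[-1]):
        raise ValueError(
            f"{what}: requested abscissa outside table range "
            f"[{xp[0]:g}, {xp[-1]:g}] (extrapolation of biological tables is "
            "refused, extend the table instead)"
        )
    return np.interp(x, xp, fp)


@dataclass(frozen=True)
class ZStarTable:
    """Tabulated saturation-corrected dose-mean specific energy ``z*_1D``.

    ``abscissa`` is an increasing LET_d (keV/um) or energy (MeV/u) grid;
    ``z_star_1d`` the corresponding per-event specific energy in Gy.
    Lookup interpolates linearly and errors outside the tabulated range.
    """

    abscissa: np.ndarray
    z_star_1d: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abscissa, dtype=float)
        z = np.asarray(self.z_star_1d, dtype=float)
        if a.ndim != 1 or a.shape != z.shape:
            raise ValueError("abscissa and z_star_1d must be 1-D and equal length")
        if not np.all(np.diff(a) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(z < 0):
            raise ValueError("z_star_1d must be >= 0")
        object.__setattr__(self, "abscissa", a)
        object.__setattr__(self, "z_star_1d", z)

    def __call__(self, x) -> np.ndarray:
        return _interp_strict(x, self.abscissa, self.z_star_1d, "ZStarTable")


@dataclass(frozen=True)
class LEMTable:
    """Intrinsic LEM inputs on an energy or LET grid.

    ``alpha_z`` (Gy^-1) is required; ``beta_z`` (Gy^-2) may be absent and is
    then derived from ``s_max`` via :func:`lem_beta_z`; ``d1`` (Gy, the
    single-traversal dose) may be absent and is then computed from LET via
    :func:`single_traversal_dose`.
    """

    abscissa: np.ndarray
    alpha_z: np.ndarray
    beta_z: np.ndarray | None = None
    s_max: float | None = None  # Gy^-1, maximum photon slope
    d1: np.ndarray | None = None  # Gy

    def __post_init__(self) -> None:
        a = np.asarray(self.abscissa, dtype=float)
        az = np.asarray(self.alpha_z, dtype=float)
        if not np.all(np.diff(a) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if a.shape != az.shape:
            raise ValueError("abscissa and alpha_z must have equal length")
        if np.any(az <= 0):
            raise ValueError("alpha_z must be > 0")
        object.__setattr__(self, "abscissa", a)
        object.__setattr__(self, "alpha_z", az)
        for name in ("beta_z", "d1"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != a.shape:
                    raise ValueError(f"{name} must match abscissa length")
                if np.any(v < 0):
                    raise ValueError(f"{name} must be >= 0")
                object.__setattr__(self, name, v)

    def alpha_z_at(self, x) -> np.ndarray:
        return _interp_strict(x, self.abscissa, self.alpha_z, "LEMTable.alpha_z")

    def beta_z_at(self, x, tissue: TissueParams | None = None) -> np.ndarray:
        if self.beta_z is not None:
            return _interp_strict(x, self.abscissa, self.beta_z, "LEMTable.beta_z")
        if tissue is None:
            raise ValueError("beta_z absent; need a tissue with D_t to derive it")
        s_max = self.s_max if self.s_max is not None else tissue.s_max
        az = self.alpha_z_at(x)
        return lem_beta_z(s_max, az, tissue.d_t if tissue.d_t is not None else math.nan)

    def d1_at(self, x) -> np.ndarray:
        if self.d1 is None:
            raise ValueError("d1 absent from table; compute from LET instead")
        return _interp_strict(x, self.abscissa, self.d1, "LEMTable.d1")


# ---------------------------------------------------------------------------
# DDM
# ---------------------------------------------------------------------------

def rescale_let(
    let: float,
    coeffs: DDMCoefficients = DDMCoefficients(),
    mode: Literal["track_segment", "clinical"] = "track_segment",
) -> float:
    """Rescaled LET ``L*`` feeding the DDM.

    In ``track_segment`` mode (the default, used for in-silico model
    comparison) ``L* = LET``.  In ``clinical`` mode the reference-photon LET
    is swapped for the Co-60 one: ``L* = LET - LET_x + LET_Co60``; both
    constants must then be configured on ``coeffs``.
    """
    if let < 0:
        raise ValueError(f"LET must be >= 0, got {let}")
    if mode == "track_segment":
        return let
    if mode == "clinical":
        if coeffs.let_x is None or coeffs.let_co60 is None:
            raise ValueError(
                "clinical L* rescaling needs let_x and let_co60 configured"
            )
        return let - coeffs.let_x + coeffs.let_co60
    raise ValueError(f"unknown mode {mode!r}")


def ddm_rbe_alpha(
    l_star: float, tissue: TissueParams, coeffs: DDMCoefficients = DDMCoefficients()
) -> float:
    """DDM initial RBE: ``1 + [k0 + (a/b)_x^-1] k1 L* exp(-k2 L*^2)``."""
    if l_star < 0:
        raise ValueError(f"L* must be >= 0, got {l_star}")
    ab = tissue.alpha_beta_x
    if ab == 0:
        raise ValueError("(alpha/beta)_x must be nonzero")
    return 1.0 + (coeffs.k0 + 1.0 / ab) * coeffs.k1 * l_star * math.exp(
        -coeffs.k2 * l_star * l_star
    )


def ddm_r_beta(l_star: float, coeffs: DDMCoefficients = DDMCoefficients()) -> float:
    """DDM quadratic ratio: ``b0 exp(-((L*-b1)/b2)^2)``, zero above the cutoff.

    The Gaussian peaks at ``L* = b1`` (~63 keV/um); above ``rbeta_cutoff``
    (default 100 keV/um) ``R_beta`` is clamped to exactly zero, implementing
    the published statement that it drops to zero there rather than following
    the still-sizeable Gaussian tail.
    """
    if l_star < 0:
        raise ValueError(f"L* must be >= 0, got {l_star}")
    if l_star > coeffs.rbeta_cutoff:
        return 0.0
    u = (l_star - coeffs.b1) / coeffs.b2
    return coeffs.b0 * math.exp(-u * u)


# ---------------------------------------------------------------------------
# modified MKM
# ---------------------------------------------------------------------------

def mkm_rbe_alpha(z_star: float, tissue: TissueParams) -> float:
    """Modified-MKM initial RBE: ``1 + z*_1D / (alpha/beta)_x``."""
    if z_star < 0:
        raise ValueError(f"z*_1D must be >= 0, got {z_star}")
    ab = tissue.alpha_beta_x
    if ab == 0:
        raise ValueError("(alpha/beta)_x must be nonzero")
    return 1.0 + z_star / ab


def mkm_r_beta() -> float:
    """Modified-MKM quadratic ratio: identically 1 (``beta = beta_x``)."""
    return 1.0


# ---------------------------------------------------------------------------
# LEM low-dose approximation
# ---------------------------------------------------------------------------

def lem_beta_z(s_max: float, alpha_z, d_t: float):
    """Intrinsic ``beta_z ~ (s_max - alpha_z)/(2 D_t)``, clamped at zero.

    Negative values (arising at high LET where ``alpha_z > s_max``) are
    forced to zero.  Accepts scalar or array ``alpha_z``.
    """
    if not d_t > 0:  # also rejects nan
        raise ValueError("D_t must be > 0 (tissue without D_t cannot use LEM)")
    bz = (s_max - np.asarray(alpha_z, dtype=float)) / (2.0 * d_t)
    bz = np.maximum(bz, 0.0)
    return float(bz) if bz.ndim == 0 else bz


def single_traversal_dose(let: float, params: MKMParams = MKMParams()) -> float:
    """Dose ``d_1`` (Gy) deposited by one particle traversing the nucleus.

    Fluence-dose conversion at unit density over the nucleus cross section:
    ``d_1 = 0.1602 * LET / (pi * R_n**2)`` with LET in keV/um and ``R_n``
    in um.
    """
    if let < 0:
        raise ValueError(f"LET must be >= 0, got {let}")
    return KEV_PER_UM3_TO_GY * let / (math.pi * params.r_nucleus**2)


def lem_rbe_alpha(alpha_z: float, d1: float, tissue: TissueParams) -> float:
    """LEM low-dose initial RBE: ``(1 - exp(-alpha_z d1)) / (alpha_x d1)``.

    The ``d1 -> 0`` limit ``alpha_z / alpha_x`` is used below ``d1 < 1e-12``.
    """
    if d1 < 0:
        raise ValueError(f"d1 must be >= 0, got {d1}")
    if tissue.alpha_x == 0:
        raise ValueError("alpha_x must be > 0 for LEM RBE_alpha")
    if d1 < 1e-12:
        return alpha_z / tissue.alpha_x
    return -math.expm1(-alpha_z * d1) / (tissue.alpha_x * d1)


def lem_r_beta(
    alpha: float, alpha_z: float, beta_z: float, tissue: TissueParams
) -> float:
    """LEM quadratic ratio: ``(alpha/alpha_z)**2 * (beta_z/beta_x)``.

    ``alpha`` is the macroscopic coefficient ``RBE_alpha * alpha_x``.
    """
    if alpha_z <= 0:
        raise ValueError(f"alpha_z must be > 0, got {alpha_z}")
    if tissue.beta_x <= 0:
        raise ValueError("beta_x must be > 0 for R_beta")
    return (alpha / alpha_z) ** 2 * (beta_z / tissue.beta_x)


# ---------------------------------------------------------------------------
# uniform adapter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Quality:
    """Radiation-quality inputs for one model evaluation (internal)."""

    l_star: float | None = None
    z_star: float | None = None
    alpha_z: float | None = None
    beta_z: float | None = None
    d1: float | None = None


def model_lq(
    model: Literal["ddm", "mkm", "lem"],
    tissue: TissueParams,
    *,
    l_star: float | None = None,
    z_star: float | None = None,
    alpha_z: float | None = None,
    beta_z: float | None = None,
    d1: float | None = None,
    coeffs: DDMCoefficients = DDMCoefficients(),
) -> LQPair:
    """Macroscopic LQ pair ``(RBE_alpha*alpha_x, R_beta*beta_x)`` for a model.

    Model-specific quality inputs: DDM needs ``l_star``; MKM needs
    ``z_star``; LEM needs ``alpha_z``, ``beta_z`` and ``d1``.
    """
    if model == "ddm":
        if l_star is None:
            raise ValueError("ddm requires l_star")
        ra = ddm_rbe_alpha(l_star, tissue, coeffs)
        rb = ddm_r_beta(l_star, coeffs)
    elif model == "mkm":
        if z_star is None:
            raise ValueError("mkm requires z_star")
        ra = mkm_rbe_alpha(z_star, tissue)
        rb = mkm_r_beta()
    elif model == "lem":
        if alpha_z is None or beta_z is None or d1 is None:
            raise ValueError("lem requires alpha_z, beta_z and d1")
        ra = lem_rbe_alpha(alpha_z, d1, tissue)
        rb = lem_r_beta(ra * tissue.alpha_x, alpha_z, beta_z, tissue)
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    return LQPair(alpha=ra * tissue.alpha_x, beta=rb * tissue.beta_x)
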