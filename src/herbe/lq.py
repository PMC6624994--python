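"""Linear-quadratic survival algebra and isoeffect RBE.

The linear-quadratic (LQ) model describes clonogenic survival after a dose
``D`` of ionizing radiation as ``S = exp(-(alpha*D + beta*D**2))``.  RBE, the
relative biological effectiveness of a particle beam, is the isoeffective dose
ratio ``D_x / D_p`` between the reference photon radiation and the particle
radiation at equal survival.  Within the LQ framework the RBE admits a closed
form in terms of the photon ratio ``(alpha/beta)_x``, the particle dose, the
initial RBE ``RBE_alpha = alpha/alpha_x`` and the quadratic-coefficient ratio
``R_beta = beta/beta_x``::

    RBE = -(a/b)_x / (2 D)
          + sqrt((a/b)_x**2 / 4 + RBE_a (a/b)_x D + R_b D**2) / D

with the continuity limit ``RBE -> RBE_alpha`` as ``D -> 0``.  This module
holds that algebra: survival, isoeffect inversion, the closed form, biological
dose and the equivalent uniform dose (EUD).

All doses are physical Gy; biological dose ``D_RBE = RBE * D`` carries the
unit Gy (RBE) and is kept distinct through :class:`RBEPoint`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "TissueParams",
    "LQPair",
    "RBEPoint",
    "LQValidityWarning",
    "lq_survival",
    "lq_effect",
    "isoeffective_photon_dose",
    "rbe_experimental",
    "rbe_closed_form",
    "eud",
]


class LQValidityWarning(UserWarning):
    """Isoeffective photon dose exceeded the LEM transition dose ``D_t``.

    Above ``D_t`` the photon survival curve is taken as purely exponential
    with maximum slope ``s_max = alpha_x + 2 beta_x D_t``; the LQ inversion
    used here extrapolates the quadratic instead.  The value is still
    returned — callers working in a LEM context should stay below ``D_t``.
    """


@dataclass(frozen=True)
class TissueParams:
    """Photon LQ radiosensitivity of one tissue.

    Parameters
    ----------
    alpha_x, beta_x
        Photon linear (Gy^-1) and quadratic (Gy^-2) LQ coefficients.
    alpha_beta_x
        The ratio ``(alpha/beta)_x`` in Gy.  Derived from ``alpha_x/beta_x``
        when omitted; if supplied it must agree with the coefficients.
    d_t
        LEM transition dose in Gy (photon curve exponential above it).
        Required only for LEM computations.
    label
        Free-text tissue tag.
    """

    alpha_x: float
    beta_x: float
    alpha_beta_x: float | None = None
    d_t: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.alpha_x < 0:
            raise ValueError(f"alpha_x must be >= 0, got {self.alpha_x}")
        if self.beta_x < 0:
            raise ValueError(f"beta_x must be >= 0, got {self.beta_x}")
        if self.alpha_beta_x is None:
            if self.beta_x > 0:
                object.__setattr__(self, "alpha_beta_x", self.alpha_x / self.beta_x)
            else:
                object.__setattr__(self, "alpha_beta_x", math.inf)
        elif self.beta_x > 0 and math.isfinite(self.alpha_beta_x):
            if abs(self.alpha_beta_x - self.alpha_x / self.beta_x) >= 1e-9:
                raise ValueError(
                    f"alpha_beta_x={self.alpha_beta_x} inconsistent with "
                    f"alpha_x/beta_x={self.alpha_x / self.beta_x}"
                )
        if self.d_t is not None and self.d_t <= 0:
            raise ValueError(f"D_t must be > 0, got {self.d_t}")

    @property
    def s_max(self) -> float:
        """Maximum photon slope ``alpha_x + 2 beta_x D_t`` (Gy^-1)."""
        if self.d_t is None:
            raise ValueError(f"tissue {self.label!r} has no D_t; s_max undefined")
        return self.alpha_x + 2.0 * self.beta_x * self.d_t


@dataclass(frozen=True)
class LQPair:
    """Linear and quadratic LQ coefficients of a (particle) radiation."""

    alpha: float  # Gy^-1
    beta: float  # Gy^-2

    def __post_init__(self) -> None:
        if self.alpha < 0:
            # survival fits on noisy data may legitimately land slightly
            # negative; keep the value but flag it
            warnings.warn(
                f"negative alpha ({self.alpha:.4g} Gy^-1) in LQPair",
                UserWarning,
                stacklevel=3,
            )
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class RBEPoint:
    """An (physical dose, RBE, biological dose) triple.

    ``d_rbe`` is in Gy (RBE) and always equals ``rbe * dose``.
    """

    dose: float
    rbe: float
    d_rbe: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if self.rbe <= 0:
            raise ValueError(f"rbe must be > 0, got {self.rbe}")
        if math.isnan(self.d_rbe):
            object.__setattr__(self, "d_rbe", self.rbe * self.dose)
        elif abs(self.d_rbe - self.rbe * self.dose) > 1e-12:
            raise ValueError("d_rbe must equal rbe * dose")


def lq_effect(lq: LQPair, dose: float) -> float:
    """Natural-log cell kill ``E = alpha*D + beta*D**2`` at ``dose`` Gy."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    return lq.alpha * dose + lq.beta * dose * dose


def lq_survival(lq: LQPair, dose: float) -> float:
    """Surviving fraction ``exp(-(alpha*D + beta*D**2))``; 1 at zero dose."""
    return math.exp(-lq_effect(lq, dose))


def isoeffective_photon_dose(tissue: TissueParams, effect: float) -> float:
    """Photon dose producing log cell kill ``effect`` in ``tissue``.

    Inverts ``beta_x*D**2 + alpha_x*D = E`` taking the positive root; the
    ``beta_x = 0`` case degenerates to ``E / alpha_x``.  If the tissue has a
    LEM transition dose and the result exceeds it, an
    :class:`LQValidityWarning` is emitted (the LQ value is still returned).
    """
    if effect < 0:
        raise ValueError(f"effect must be >= 0, got {effect}")
    if tissue.alpha_x == 0 and tissue.beta_x == 0:
        raise ValueError("degenerate tissue: alpha_x and beta_x both zero")
    if effect == 0:
        return 0.0
    if tissue.beta_x == 0:
        dx = effect / tissue.alpha_x
    else:
        # positive root of beta_x D^2 + alpha_x D - E = 0
        dx = (
            -tissue.alpha_x
            + math.sqrt(tissue.alpha_x**2 + 4.0 * tissue.beta_x * effect)
        ) / (2.0 * tissue.beta_x)
    if tissue.d_t is not None and dx > tissue.d_t:
        warnings.warn(
            f"isoeffective photon dose {dx:.3f} Gy exceeds D_t={tissue.d_t} Gy; "
            "LQ inversion extrapolated beyond its validity range",
            LQValidityWarning,
            stacklevel=2,
        )
    return dx


def rbe_experimental(tissue: TissueParams, ion: LQPair, dose: float) -> RBEPoint:
    """Isoeffect RBE of an ion radiation with LQ coefficients ``ion``.

    ``RBE = D_x / D`` where ``D_x`` is the photon dose isoeffective with the
    ion effect ``alpha*D + beta*D**2``.  Undefined at ``dose = 0``; use
    :func:`rbe_closed_form`, whose zero-dose limit is ``RBE_alpha``.
    """
    if dose <= 0:
        raise ValueError("dose must be > 0; the D->0 limit is RBE_alpha")
    dx = isoeffective_photon_dose(tissue, lq_effect(ion, dose))
    return RBEPoint(dose=dose, rbe=dx / dose)


def rbe_closed_form(
    tissue: TissueParams, dose: float, rbe_alpha: float, r_beta: float
) -> RBEPoint:
    """Closed-form LQ isoeffect RBE from ``(RBE_alpha, R_beta)``.

    Equivalent to :func:`rbe_experimental` with ion coefficients
    ``alpha = RBE_alpha * alpha_x`` and ``beta = R_beta * beta_x``.  At
    ``dose = 0`` returns the analytic continuity limit ``RBE = RBE_alpha``.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if rbe_alpha <= 0:
        raise ValueError(f"rbe_alpha must be > 0, got {rbe_alpha}")
    if r_beta < 0:
        raise ValueError(f"r_beta must be >= 0, got {r_beta}")
    ab = tissue.alpha_beta_x
    if not math.isfinite(ab):
        raise ValueError("closed form requires beta_x > 0 (finite (alpha/beta)_x)")
    # rationalized form of -(a/b)_x/(2D) + sqrt((a/b)_x^2/4 + RBE_a (a/b)_x D
    # + R_b D^2)/D: algebraically identical, numerically stable at small D,
    # and yielding the continuity limit RBE_alpha exactly at D = 0
    rbe = (rbe_alpha * ab + r_beta * dose) / (
        ab / 2.0 + math.sqrt(ab * ab / 4.0 + rbe_alpha * ab * dose + r_beta * dose * dose)
    )
    return RBEPoint(dose=dose, rbe=rbe)


def eud(tissue: TissueParams, mean_survival: float) -> float:
    """Equivalent uniform dose (Gy) for mean target survival ``S_bar``.

    ``EUD = -(a/b)_x/2 + sqrt((a/b)_x**2/4 - ln(S_bar)/beta_x)`` — the uniform
    photon dose a tissue would need to receive for its LQ survival to equal
    the (voxel-averaged) survival actually achieved.
    """
    if not 0.0 < mean_survival <= 1.0:
        raise ValueError(f"mean_survival must be in (0, 1], got {mean_survival}")
    if tissue.beta_x <= 0:
        raise ValueError("EUD formula requires beta_x > 0")
    ab = tissue.alpha_beta_x
    return -ab / 2.0 + math.sqrt(ab * ab / 4.0 - math.log(mean_survival) / tissue.beta_x)
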