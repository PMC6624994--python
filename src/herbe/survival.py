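"""Clonogenic-survival analysis: LQ fitting and experimental RBE extraction.

Survival data from colony-formation assays arrive as (dose, surviving
fraction, uncertainty) records per radiation and condition.  Fitting is
weighted least squares on log survival — the LQ model is linear in
``(alpha, beta)`` there — with a nonnegativity constraint on ``beta``.
Weights are ``n / (sd/SF)**2`` when a standard deviation is supplied
(delta-method variance of ``ln SF``) and the replicate count otherwise.
A seeded bootstrap provides alternative standard errors for
heteroscedastic data.

Isoeffect RBE versus dose follows by applying the photon fit as the
reference tissue and the ion fit as the particle radiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .lq import LQPair, RBEPoint, TissueParams, rbe_experimental

__all__ = [
    "SurvivalDataset",
    "LQFit",
    "fit_lq",
    "rbe_vs_dose",
    "model_vs_experiment",
]


@dataclass
class SurvivalDataset:
    """Clonogenic measurements: one record per (dose, condition) point.

    ``sd`` is the standard deviation of the surviving fraction (optional,
    NaN where absent); ``n_replicates`` the number of wells/replicates
    behind each mean.  Surviving fractions slightly above 1 are tolerated
    (low-dose counting noise) up to 1.5, with a warning above 1.
    """

    dose: np.ndarray  # Gy
    surviving_fraction: np.ndarray
    sd: np.ndarray | None = None
    n_replicates: np.ndarray | None = None
    radiation_label: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)
        if self.dose.shape != self.surviving_fraction.shape:
            raise ValueError("dose and surviving_fraction must match in length")
        if np.any(self.dose < 0):
            raise ValueError("doses must be >= 0")
        if np.any(self.surviving_fraction > 1.5):
            raise ValueError("surviving fraction > 1.5 is not credible data")
        if np.any(self.surviving_fraction > 1.0):
            warnings.warn(
                "surviving fraction above 1 (noise at low dose?); kept",
                UserWarning,
                stacklevel=2,
            )
        for attr in ("sd", "n_replicates"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.dose.shape:
                    raise ValueError(f"{attr} must match dose length")
                setattr(self, attr, v)

    def __len__(self) -> int:
        return self.dose.size


@dataclass
class LQFit:
    """Fitted LQ parameters with uncertainties and diagnostics."""

    lq: LQPair
    se_alpha: float
    se_beta: float
    cov_alpha_beta: float
    residual_norm: float  # weighted RSS
    dof: int
    n_points: int
    beta_clamped: bool = False
    bootstrap_se: tuple[float, float] | None = None

    @property
    def alpha_beta(self) -> float:
        """Fitted ratio ``alpha/beta`` in Gy (inf when beta = 0)."""
        if self.lq.beta > 0:
            return self.lq.alpha / self.lq.beta
        return float("inf")


def _weights(data: SurvivalDataset, sf: np.ndarray, keep: np.ndarray) -> np.ndarray:
    n = (
        data.n_replicates[keep]
        if data.n_replicates is not None
        else np.ones(keep.sum())
    )
    n = np.where(np.isfinite(n) & (n > 0), n, 1.0)
    if data.sd is not None:
        sd = data.sd[keep]
        rel = np.where(np.isfinite(sd) & (sd > 0), (sd / sf) ** 2, np.nan)
        # records without a usable sd fall back to the median relative variance
        fallback = np.nanmedian(rel) if np.any(np.isfinite(rel)) else 1.0
        rel = np.where(np.isfinite(rel), rel, fallback)
        return n / rel
    return n


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns coef, covariance, weighted RSS, dof."""
    sw = np.sqrt(w)
    xw = x * sw[:, None]
    yw = y * sw
    coef, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ coef
    rss = float(resid @ resid)
    dof = max(len(y) - x.shape[1], 1)
    xtx_inv = np.linalg.inv(xw.T @ xw)
    cov = xtx_inv * (rss / dof)
    return coef, cov, rss, dof


def fit_lq(
    data: SurvivalDataset,
    *,
    bootstrap: int = 0,
    seed: int | None = None,
) -> LQFit:
    """Fit LQ coefficients to a survival dataset.

    Minimizes ``sum w_i (ln SF_i + alpha D_i + beta D_i**2)**2`` with
    ``beta >= 0`` (refit on the linear model when the unconstrained beta is
    negative).  Records with ``SF <= 0`` are excluded with a warning.  With
    ``bootstrap > 0``, that many case resamples (seeded) provide additional
    standard errors.
    """
    sf_all = data.surviving_fraction
    keep = sf_all > 0
    if np.any(~keep):
        warnings.warn(
            f"excluding {int((~keep).sum())} record(s) with SF <= 0 from the fit",
            UserWarning,
            stacklevel=2,
        )
    dose = data.dose[keep]
    sf = sf_all[keep]
    if np.unique(dose).size < 3:
        raise ValueError("need at least 3 distinct dose levels to fit the LQ model")
    y = -np.log(sf)
    x = np.column_stack([dose, dose**2])
    w = _weights(data, sf, keep)

    coef, cov, rss, dof = _wls(x, y, w)
    clamped = False
    if coef[1] < 0:
        clamped = True
        c1, cov1, rss, dof = _wls(x[:, :1], y, w)
        coef = np.array([c1[0], 0.0])
        cov = np.array([[cov1[0, 0], 0.0], [0.0, 0.0]])

    boot_se = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        draws = np.empty((bootstrap, 2))
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            if np.unique(dose[idx]).size < 2:
                idx = np.arange(n)
            cb, *_ = _wls(x[idx], y[idx], w[idx])
            if cb.size == 2 and cb[1] < 0:
                cb1, *_ = _wls(x[idx][:, :1], y[idx], w[idx])
                cb = np.array([cb1[0], 0.0])
            draws[b] = cb
        boot_se = (float(draws[:, 0].std(ddof=1)), float(draws[:, 1].std(ddof=1)))

    return LQFit(
        lq=LQPair(alpha=float(coef[0]), beta=float(coef[1])),
        se_alpha=float(np.sqrt(cov[0, 0])),
        se_beta=float(np.sqrt(cov[1, 1])),
        cov_alpha_beta=float(cov[0, 1]),
        residual_norm=rss,
        dof=dof,
        n_points=int(keep.sum()),
        beta_clamped=clamped,
        bootstrap_se=boot_se,
    )


def rbe_vs_dose(
    photon_fit: LQFit, ion_fit: LQFit, doses
) -> list[RBEPoint]:
    """Isoeffect RBE at each helium dose, from fitted photon/ion LQ pairs."""
    tissue = TissueParams(
        alpha_x=photon_fit.lq.alpha, beta_x=photon_fit.lq.beta, label="photon fit"
    )
    return [rbe_experimental(tissue, ion_fit.lq, float(d)) for d in np.atleast_1d(doses)]


def model_vs_experiment(
    model_points: list[RBEPoint], experiment_points: list[RBEPoint]
) -> np.ndarray:
    """Percent RBE difference ``100*(model-exp)/exp`` on a shared dose grid."""
    md = np.array([p.dose for p in model_points])
    ed = np.array([p.dose for p in experiment_points])
    if md.shape != ed.shape or not np.allclose(md, ed):
        raise ValueError("model and experiment must share the same dose grid")
    m = np.array([p.rbe for p in model_points])
    e = np.array([p.rbe for p in experiment_points])
    return 100.0 * (m - e) / e
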