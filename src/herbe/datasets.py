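"""Packaged reference tables: tissue parameters and measured LQ fits."""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .lq import LQPair, TissueParams

__all__ = ["tissue_table", "load_tissue", "helium_lq_table", "helium_lq_row"]


def _data_path(name: str):
    return resources.files("herbe.data") / name


def tissue_table() -> dict[str, dict]:
    """Raw tissue table as a dict of records (printed values verbatim)."""
    with resources.as_file(_data_path("tissues.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def load_tissue(key: str) -> TissueParams:
    """A packaged tissue as :class:`TissueParams`.

    The ratio ``(alpha/beta)_x`` is derived from the coefficients; printed
    (rounded) ratios remain available via :func:`tissue_table`.
    """
    table = tissue_table()
    if key not in table:
        raise KeyError(f"unknown tissue {key!r}; available: {sorted(table)}")
    rec = table[key]
    return TissueParams(
        alpha_x=float(rec["alpha_x"]),
        beta_x=float(rec["beta_x"]),
        d_t=float(rec["d_t"]) if rec.get("d_t") is not None else None,
        label=str(rec.get("label", key)),
    )


def helium_lq_table() -> pd.DataFrame:
    """Measured photon/helium LQ fit parameters (Renca cells, exp. A and B).

    Columns hold the printed numbers verbatim, including the printed
    ``alpha_beta_x_printed`` ratio.  The added boolean
    ``alpha_beta_consistent`` flags rows where the printed ratio agrees with
    ``alpha_x / beta_x`` to printed precision — the experiment-A rows print
    1.79 while the coefficients give 1.89, a source inconsistency that is
    flagged, not resolved.
    """
    with resources.as_file(_data_path("clonogenic_lq_fits.csv")) as p:
        df = pd.read_csv(p, comment="#")
    df["alpha_beta_consistent"] = (
        np.abs(df["alpha_beta_x_printed"] - df["alpha_x"] / df["beta_x"]) < 0.005
    )
    return df


def helium_lq_row(experiment: str, let_d: float) -> tuple[TissueParams, LQPair]:
    """The (photon tissue, helium LQ pair) of one measured condition."""
    df = helium_lq_table()
    match = df[(df["experiment"] == experiment) & (np.isclose(df["let_d"], let_d))]
    if len(match) != 1:
        raise KeyError(f"no unique row for experiment={experiment!r}, let_d={let_d}")
    r = match.iloc[0]
    tissue = TissueParams(
        alpha_x=float(r["alpha_x"]),
        beta_x=float(r["beta_x"]),
        label=f"Renca photon baseline (exp. {experiment})",
    )
    return tissue, LQPair(alpha=float(r["alpha"]), beta=float(r["beta"]))
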