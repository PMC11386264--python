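"""Residual diagnostics: Glejser heteroscedasticity test and data exports."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

from .estimation import FittedModel, fit_ols
from .inference import partial_test_all, simultaneous_test

__all__ = ["GlejserResult", "glejser_test", "export_diagnostics"]

HOMOSCEDASTIC = "homoscedastic"
HETEROSCEDASTIC = "heteroscedastic"


@dataclass
class GlejserResult:
    """Outcome of the Glejser auxiliary regression of |residuals| on the design."""

    simultaneous_p: float
    per_term: pd.DataFrame  # per-coefficient partial-test table
    conclusion: str  # HOMOSCEDASTIC | HETEROSCEDASTIC
    auxiliary: FittedModel | None = None


def glejser_test(
    model: FittedModel, alpha: float = 0.05, center: bool = True
) -> GlejserResult:
    """Regress absolute residuals on the *same* design used for the primary fit.

    The full Fourier design (including the cosine columns) is reused; the
    per-term p-values come from the auxiliary regression's partial t-tests.
    The model is called homoscedastic when the simultaneous p-value is >=
    alpha.

    With ``center=True`` (default) the overall significance is the
    mean-corrected regression F-test, F = [(SST - Q)/(rank-1)] / [Q/(n-rank)]
    on F(rank-1, n-rank).  Absolute residuals always have a positive mean, so
    the uncorrected explained-vs-residual ratio (``center=False``, the same
    form as the primary simultaneous statistic) is dominated by the intercept
    and rejects regardless of heteroscedasticity; only the centered form is
    calibrated as a diagnostic.
    """
    abs_resid = np.abs(model.residuals)
    if float(abs_resid.max(initial=0.0)) <= 1e-12:
        warnings.warn(
            "residuals are identically zero; Glejser test degenerate", stacklevel=2
        )
        empty = pd.DataFrame(
            columns=["Parameter", "Estimation", "Statistic |Z|", "P-value", "Decision"]
        )
        return GlejserResult(
            simultaneous_p=1.0, per_term=empty, conclusion=HOMOSCEDASTIC
        )

    aux = fit_ols(model.design, abs_resid)
    if center:
        df1 = aux.df_model - 1
        df2 = aux.df_resid
        sst = float(np.sum((abs_resid - abs_resid.mean()) ** 2))
        if df1 < 1 or sst <= 0.0:
            warnings.warn("degenerate Glejser auxiliary regression", stacklevel=2)
            sim_p = 1.0
        else:
            f_stat = ((sst - aux.rss) / df1) / (aux.rss / df2)
            sim_p = float(stats.f.sf(f_stat, df1, df2))
    else:
        sim_p = simultaneous_test(aux, alpha=alpha).p_value
    per_term = partial_test_all(aux, alpha=alpha)
    conclusion = HETEROSCEDASTIC if sim_p < alpha else HOMOSCEDASTIC
    return GlejserResult(
        simultaneous_p=sim_p,
        per_term=per_term,
        conclusion=conclusion,
        auxiliary=aux,
    )


def export_diagnostics(model: FittedModel) -> pd.DataFrame:
    """Actual/predicted/residual series as a plain table for external plotting."""
    return pd.DataFrame(
        {
            "index": np.arange(model.n),
            "actual": model.y,
            "predicted": model.fitted,
            "residual": model.residuals,
        }
    )
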