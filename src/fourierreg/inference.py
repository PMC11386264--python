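"""Likelihood-ratio-derived hypothesis tests for the Fourier-basis fit.

The simultaneous test compares the explained quadratic form (X delta_hat)'y
against the residual sum of squares and refers the ratio to an F
distribution with (rank(X), n - rank(X)) degrees of freedom.

The partial test for a single coefficient delta_l is obtained by comparing
the unconstrained fit to a Lagrange-multiplier constrained fit under
a_l delta = 0, where a_l is the selector row vector for coefficient l.  The
resulting statistic

    Z = a_l delta_hat / sqrt((Q / r) * a_l (X'X)^+ a_l')

follows a Student t distribution with r = n - rank(X) degrees of freedom
under the null.  All (X'X)^{-1} occurrences use the shared pseudoinverse so
that the rank-deficient half-constant columns are handled in the
minimum-norm sense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import DesignMatrix
from .estimation import FittedModel, hat_matrix
from .exceptions import EstimabilityError, SaturatedModelError, SpecificationError

__all__ = [
    "TestResult",
    "Constraint",
    "ConstrainedFit",
    "simultaneous_test",
    "constrained_fit",
    "partial_test",
    "partial_test_all",
    "likelihood_ratio",
    "quadratic_form_check",
]

REJECT = "reject"
FAIL_TO_REJECT = "fail-to-reject"


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its reference distribution and decision at alpha."""

    statistic: float
    dist: str  # "F" or "t"
    df: tuple[int, ...]  # (df1, df2) for F, (r,) for t
    critical_value: float
    p_value: float
    alpha: float
    decision: str  # REJECT | FAIL_TO_REJECT


@dataclass(frozen=True)
class Constraint:
    """Single-coefficient selector a_l: 1 at (0-based) position ``index``, else 0."""

    index: int

    def __post_init__(self) -> None:
        if int(self.index) < 0:
            raise SpecificationError(f"coefficient index must be >= 0, got {self.index}")
        object.__setattr__(self, "index", int(self.index))

    def selector(self, L: int) -> np.ndarray:
        if self.index >= L:
            raise SpecificationError(
                f"coefficient index {self.index} out of range for L={L}"
            )
        a = np.zeros(L)
        a[self.index] = 1.0
        return a


@dataclass
class ConstrainedFit:
    """Least-squares fit under the single linear constraint a_l delta = 0."""

    delta_omega: np.ndarray
    theta_hat: float
    sigma2_omega: float  # (y - X delta_omega)'(y - X delta_omega) / n
    rss_omega: float
    constraint: Constraint


def _estimability_weight(model: FittedModel, c: Constraint) -> float:
    """a_l (X'X)^+ a_l' for a selector constraint; must be positive."""
    if c.index >= model.L:
        raise SpecificationError(
            f"coefficient index {c.index} out of range for L={model.L}"
        )
    d = float(model.gram_pinv[c.index, c.index])
    scale = max(1.0, float(np.abs(np.diag(model.gram_pinv)).max()))
    if d <= 1e-12 * scale:
        raise EstimabilityError(
            f"constraint direction for coefficient {c.index} not estimable"
        )
    return d


def simultaneous_test(model: FittedModel, alpha: float = 0.05) -> TestResult:
    """F-test of all coefficients jointly against the all-zero null.

    Lambda = [(X delta_hat)'y / df1] / [Q / df2] with df1 = rank(X) and
    df2 = n - rank(X); the null is rejected when Lambda exceeds the upper
    alpha quantile of F(df1, df2).
    """
    df1, df2 = model.df_model, model.df_resid
    if df2 < 1:
        raise SaturatedModelError("no residual degrees of freedom for the F test")
    explained = float(model.fitted @ model.y)
    lam = (explained / df1) / (model.rss / df2)
    crit = float(stats.f.ppf(1.0 - alpha, df1, df2))
    p = float(stats.f.sf(lam, df1, df2))
    decision = REJECT if lam > crit else FAIL_TO_REJECT
    return TestResult(
        statistic=float(lam),
        dist="F",
        df=(df1, df2),
        critical_value=crit,
        p_value=p,
        alpha=alpha,
        decision=decision,
    )


def constrained_fit(model: FittedModel, c: Constraint) -> ConstrainedFit:
    """Lagrange-multiplier estimator of delta under a_l delta = 0.

    delta_omega = delta_hat - (X'X)^+ a_l' (a_l (X'X)^+ a_l')^{-1} a_l delta_hat,
    with multiplier theta_hat = (a_l (X'X)^+ a_l')^{-1} a_l delta_hat.
    """
    d = _estimability_weight(model, c)
    l = c.index
    a_delta = float(model.delta_hat[l])
    theta_hat = a_delta / d
    delta_omega = model.delta_hat - model.gram_pinv[:, l] * theta_hat
    resid = model.y - model.design.values @ delta_omega
    rss_omega = float(resid @ resid)
    return ConstrainedFit(
        delta_omega=delta_omega,
        theta_hat=theta_hat,
        sigma2_omega=rss_omega / model.n,
        rss_omega=rss_omega,
        constraint=c,
    )


def partial_test(model: FittedModel, c: Constraint, alpha: float = 0.05) -> TestResult:
    """Two-sided t-test of H0: delta_l = 0 for a single coefficient."""
    r = model.df_resid
    if r < 1:
        raise SaturatedModelError("no residual degrees of freedom for the t test")
    d = _estimability_weight(model, c)
    a_delta = float(model.delta_hat[c.index])
    scale = np.sqrt((model.rss / r) * d)
    if a_delta == 0.0:
        z = 0.0
    elif scale == 0.0:
        z = np.inf if a_delta > 0 else -np.inf
    else:
        z = a_delta / scale
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, r))
    p = 2.0 * float(stats.t.sf(abs(z), r))
    decision = REJECT if abs(z) >= crit else FAIL_TO_REJECT
    return TestResult(
        statistic=float(z),
        dist="t",
        df=(r,),
        critical_value=crit,
        p_value=p,
        alpha=alpha,
        decision=decision,
    )


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method in ("bh", "fdr_bh"):
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        return adj
    raise ValueError(f"unknown adjustment method {method!r}")


def partial_test_all(
    model: FittedModel, alpha: float = 0.05, adjust: str | None = None
) -> pd.DataFrame:
    """Run the partial t-test for every coefficient l = 0..L-1.

    Returns a table with one row per coefficient: Parameter, Estimation,
    Statistic |Z|, P-value, Decision.  No multiplicity adjustment is applied
    by default; ``adjust`` may be "bonferroni" or "bh".  Estimability
    failures are reported per-row (nan statistic, Decision "not-estimable"),
    never fatally.
    """
    rows = []
    raw_p = np.full(model.L, np.nan)
    for l in range(model.L):
        label = model.design.labels[l]
        est = float(model.delta_hat[l])
        try:
            res = partial_test(model, Constraint(l), alpha=alpha)
        except EstimabilityError:
            rows.append(
                {
                    "Parameter": label,
                    "Estimation": est,
                    "Statistic |Z|": float("nan"),
                    "P-value": float("nan"),
                    "Decision": "not-estimable",
                }
            )
            continue
        raw_p[l] = res.p_value
        rows.append(
            {
                "Parameter": label,
                "Estimation": est,
                "Statistic |Z|": abs(res.statistic),
                "P-value": res.p_value,
                "Decision": res.decision,
            }
        )
    table = pd.DataFrame(rows)
    if adjust is not None:
        ok = ~np.isnan(raw_p)
        adj = raw_p.copy()
        adj[ok] = _adjust_pvalues(raw_p[ok], adjust)
        table["P-value"] = adj
        mask = table["Decision"] != "not-estimable"
        table.loc[mask, "Decision"] = np.where(
            adj[mask.to_numpy()] < alpha, REJECT, FAIL_TO_REJECT
        )
    return table


def likelihood_ratio(model: FittedModel, c: Constraint) -> float:
    """Likelihood ratio w in (0, 1] comparing the constrained and full fits.

    w = (1 + (a_l delta_hat)^2 / (a_l (X'X)^+ a_l') / Q)^(-n/2); w = 1 iff
    the tested coefficient estimate is already zero.
    """
    d = _estimability_weight(model, c)
    a_delta = float(model.delta_hat[c.index])
    if a_delta == 0.0:
        return 1.0
    if model.rss == 0.0:
        return 0.0
    return float((1.0 + (a_delta**2 / d) / model.rss) ** (-model.n / 2.0))


def quadratic_form_check(model: FittedModel, c: Constraint) -> dict[str, float]:
    """Diagnostic identities for the quadratic-form route to Z^2.

    Forms M = X G a_l' (a_l G a_l')^{-1} a_l G X' with G = (X'X)^+ and
    reports the residuals of the identities M' = M, M^2 = M, trace(M) = 1,
    M (I - U) = 0, and Z^2 = y'My / (y'(I-U)y / r).
    """
    X = model.design.values
    G = model.gram_pinv
    d = _estimability_weight(model, c)
    g = G[:, c.index]
    v = X @ g  # X G a_l'
    M = np.outer(v, v) / d
    U = hat_matrix(model.design)
    IU = np.eye(model.n) - U

    y = model.y
    r = model.df_resid
    z2_quadform = float(y @ M @ y) / (float(y @ IU @ y) / r)
    z = partial_test(model, c).statistic
    return {
        "symmetry": float(np.abs(M - M.T).max()),
        "idempotency": float(np.abs(M @ M - M).max()),
        "trace_minus_1": float(np.trace(M) - 1.0),
        "M_times_I_minus_U": float(np.abs(M @ IU).max()),
        "z2_direct": float(z**2),
        "z2_quadform": z2_quadform,
        "z2_gap": float(abs(z**2 - z2_quadform)),
    }
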