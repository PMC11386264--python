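"""GCV scoring and oscillation-parameter search.

Two search scenarios are supported: a uniform search where every predictor
shares one oscillation count T, and a full Cartesian enumeration where each
predictor's count varies independently over 1..T_max.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import DesignMatrix, FourierSpec, assemble_design, build_predictor_block
from .estimation import FitMetrics, _compute_metrics, fit_ols, hat_matrix
from .exceptions import SaturatedModelError, SearchBudgetError, SpecificationError

__all__ = [
    "GCVResult",
    "SearchReport",
    "gcv_from_rss",
    "gcv_score",
    "search_uniform",
    "search_combinations",
]


@dataclass(frozen=True)
class GCVResult:
    """GCV score for one candidate spec, with its fit metrics and design rank."""

    spec: FourierSpec
    gcv: float
    metrics: FitMetrics
    rank: int


@dataclass
class SearchReport:
    """Outcome of an oscillation-parameter search."""

    mode: str  # "uniform" | "combinations"
    candidates_evaluated: int
    best: GCVResult
    per_candidate: pd.DataFrame  # T_1..T_p, GCV, metrics, rank; sorted by GCV

    def to_csv(self, path) -> None:
        self.per_candidate.to_csv(path, index=False)


def gcv_from_rss(rss: float, n: int, rank: int) -> float:
    """GCV = (rss / n) / ((n - rank) / n)^2.

    Because I - U is an orthogonal projector, the generic quadratic-form
    numerator y'(I-U)'(I-U)y collapses to the residual sum of squares, and
    trace(I - U) = n - rank.
    """
    if n - rank <= 0:
        raise SaturatedModelError("saturated model: trace(I - U) = 0")
    return (rss / n) / ((n - rank) / n) ** 2


def gcv_score(design: DesignMatrix, y: np.ndarray, method: str = "rank") -> GCVResult:
    """GCV score of one assembled design.

    ``method="rank"`` uses the projector identity (no n x n matrices);
    ``method="dense"`` explicitly forms I - U and evaluates the raw
    quadratic-form definition.  Both agree to floating tolerance.
    """
    model = fit_ols(design, y)
    if method == "rank":
        gcv = gcv_from_rss(model.rss, model.n, design.rank)
    elif method == "dense":
        n = model.n
        IU = np.eye(n) - hat_matrix(design)
        num = float(model.y @ (IU.T @ IU @ model.y)) / n
        den = (float(np.trace(IU)) / n) ** 2
        if den == 0.0:
            raise SaturatedModelError("saturated model: trace(I - U) = 0")
        gcv = num / den
    else:
        raise ValueError(f"unknown method {method!r}")
    return GCVResult(spec=design.spec, gcv=gcv, metrics=model.metrics, rank=design.rank)


def _candidate_row(T: tuple[int, ...], res: GCVResult) -> dict:
    row = {f"T_{j}": t for j, t in enumerate(T, start=1)}
    row["GCV"] = res.gcv
    row.update(res.metrics.as_dict())
    row["rank"] = res.rank
    return row


def _score_columns(Xc: np.ndarray, y: np.ndarray, spec: FourierSpec) -> GCVResult:
    """Fast candidate scoring via an SVD least-squares solve."""
    n = Xc.shape[0]
    coef, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
    rank = int(rank)
    if rank >= n:
        raise SaturatedModelError("saturated model: no residual degrees of freedom")
    resid = y - Xc @ coef
    rss = float(resid @ resid)
    gcv = gcv_from_rss(rss, n, rank)
    return GCVResult(
        spec=spec, gcv=gcv, metrics=_compute_metrics(y, resid, rss), rank=rank
    )


def _finish_report(
    mode: str, rows: list[dict], results: list[tuple[tuple[int, ...], GCVResult]]
) -> SearchReport:
    if not results:
        raise SaturatedModelError("no candidate had residual degrees of freedom")
    # ties broken toward parsimony: smaller sum of T_j, then lexicographic
    best = min(results, key=lambda tr: (tr[1].gcv, sum(tr[0]), tr[0]))[1]
    table = pd.DataFrame(rows).sort_values("GCV", kind="stable").reset_index(drop=True)
    return SearchReport(
        mode=mode, candidates_evaluated=len(rows), best=best, per_candidate=table
    )


def search_uniform(
    data, y: np.ndarray, T_max: int, rescale: bool = False
) -> SearchReport:
    """Evaluate uniform T = 1..T_max and return all scores plus the argmin."""
    if int(T_max) < 1:
        raise SpecificationError(f"T_max must be >= 1, got {T_max}")
    y = np.asarray(y, dtype=float).ravel()
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    p = arr.shape[1]

    rows: list[dict] = []
    results: list[tuple[tuple[int, ...], GCVResult]] = []
    for T in range(1, int(T_max) + 1):
        spec = FourierSpec.uniform(p, T, rescale=rescale)
        design = assemble_design(data, spec)
        try:
            res = gcv_score(design, y)
        except SaturatedModelError:
            warnings.warn(f"skipping uniform T={T}: design rank >= n", stacklevel=2)
            continue
        rows.append(_candidate_row(spec.T, res))
        results.append((spec.T, res))
    return _finish_report("uniform", rows, results)


def search_combinations(
    data,
    y: np.ndarray,
    T_max: int,
    rescale: bool = False,
    budget: int = 100_000,
    force: bool = False,
) -> SearchReport:
    """Full Cartesian enumeration of T-vectors in {1..T_max}^p, scored by GCV.

    Raises :class:`SearchBudgetError` when T_max**p exceeds ``budget`` unless
    ``force=True``.
    """
    if int(T_max) < 1:
        raise SpecificationError(f"T_max must be >= 1, got {T_max}")
    T_max = int(T_max)
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(data, pd.DataFrame):
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    p = arr.shape[1]

    n_candidates = T_max**p
    if n_candidates > budget and not force:
        raise SearchBudgetError(
            f"{n_candidates} combinations exceed the budget of {budget}; "
            "use search_uniform, a smaller T_max, or force=True"
        )

    # precompute each predictor's block at T_max and slice columns per candidate
    full_blocks = []
    for j in range(p):
        x = arr[:, j]
        if rescale:
            from .basis import _rescale_to_pi

            x = _rescale_to_pi(np.asarray(x, dtype=float), f"x{j + 1}")
        full_blocks.append(build_predictor_block(x, T_max))

    rows: list[dict] = []
    results: list[tuple[tuple[int, ...], GCVResult]] = []
    for combo in itertools.product(range(1, T_max + 1), repeat=p):
        Xc = np.hstack([full_blocks[j][:, : combo[j] + 2] for j in range(p)])
        spec = FourierSpec(T=combo, rescale=rescale)
        try:
            res = _score_columns(Xc, y, spec)
        except SaturatedModelError:
            warnings.warn(f"skipping T={combo}: design rank >= n", stacklevel=2)
            continue
        rows.append(_candidate_row(combo, res))
        results.append((combo, res))
    return _finish_report("combinations", rows, results)
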