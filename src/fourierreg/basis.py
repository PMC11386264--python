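"""Fourier-series basis construction.

Each predictor ``x_j`` contributes a block of ``T_j + 2`` columns to the
design matrix: a constant column fixed at 1/2, the raw linear trend ``x_j``,
and cosine harmonics ``cos(t * x_j)`` for ``t = 1..T_j``.  For ``p >= 2``
predictors the assembled design is intentionally rank-deficient: the ``p``
half-constant columns are identical, and the deficiency is resolved
downstream by minimum-norm least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputDataError, SpecificationError

__all__ = ["FourierSpec", "DesignMatrix", "build_predictor_block", "assemble_design"]


@dataclass(frozen=True)
class FourierSpec:
    """Per-predictor oscillation counts defining a Fourier-basis model.

    Parameters
    ----------
    T
        Oscillation count (number of cosine harmonics) for each predictor;
        one positive integer per predictor.
    rescale
        If True, each predictor is linearly rescaled to ``[0, pi]`` before the
        basis is evaluated.  Default is False: cosines are applied to raw
        predictor values.
    """

    T: tuple[int, ...]
    rescale: bool = False

    def __post_init__(self) -> None:
        T = tuple(int(t) for t in self.T)
        if len(T) < 1:
            raise SpecificationError("need at least one predictor (p >= 1)")
        if any(t < 1 for t in T):
            raise SpecificationError(f"every oscillation count must be >= 1, got {T}")
        object.__setattr__(self, "T", T)

    @classmethod
    def uniform(cls, p: int, T: int, rescale: bool = False) -> "FourierSpec":
        """Spec with the same oscillation count ``T`` for all ``p`` predictors."""
        if p < 1:
            raise SpecificationError("need at least one predictor (p >= 1)")
        return cls(T=(int(T),) * int(p), rescale=rescale)

    @property
    def p(self) -> int:
        """Number of predictors."""
        return len(self.T)

    @property
    def L(self) -> int:
        """Total coefficient count, sum_j (T_j + 2)."""
        return sum(t + 2 for t in self.T)

    @property
    def rank_bound(self) -> int:
        """Upper bound on the design rank: 1 + p + sum_j T_j.

        The p half-constant columns are mutually collinear, so at most one of
        them contributes to the rank.
        """
        return 1 + self.p + sum(self.T)

    def labels(self) -> list[str]:
        """Coefficient labels in design-column order (mu_j/2, beta_j, delta_tj)."""
        out: list[str] = []
        for j, Tj in enumerate(self.T, start=1):
            out.append(f"mu_{j}/2")
            out.append(f"beta_{j}")
            out.extend(f"delta_{t}{j}" for t in range(1, Tj + 1))
        return out


@dataclass
class DesignMatrix:
    """Assembled n x L Fourier design with column-block bookkeeping."""

    values: np.ndarray
    spec: FourierSpec
    blocks: tuple[slice, ...]
    labels: tuple[str, ...]
    rank: int
    predictor_names: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def L(self) -> int:
        return self.values.shape[1]

    def block(self, j: int) -> np.ndarray:
        """Columns belonging to predictor ``j`` (0-based)."""
        return self.values[:, self.blocks[j]]


def _validate_predictor(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise SpecificationError(f"{name} must be one-dimensional, got shape {x.shape}")
    if x.size < 1:
        raise SpecificationError(f"{name} must have at least one row")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise InputDataError(
            f"non-finite value in {name} at row {bad[0]}"
            + (f" (and {bad.size - 1} more rows)" if bad.size > 1 else "")
        )
    return x


def build_predictor_block(x: Sequence[float] | np.ndarray, T_j: int) -> np.ndarray:
    """Build the n x (T_j + 2) basis block for a single predictor.

    Column 0 is the constant 1/2, column 1 is ``x`` itself, and columns
    ``2..T_j+1`` are ``cos(t * x)`` for ``t = 1..T_j`` in increasing order.
    """
    if int(T_j) < 1:
        raise SpecificationError(f"oscillation count must be >= 1, got {T_j}")
    T_j = int(T_j)
    x = _validate_predictor(np.asarray(x))
    n = x.size
    block = np.empty((n, T_j + 2), dtype=float)
    block[:, 0] = 0.5
    block[:, 1] = x
    t = np.arange(1, T_j + 1)
    block[:, 2:] = np.cos(np.outer(x, t))
    return block


def _rescale_to_pi(x: np.ndarray, name: str) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise InputDataError(f"cannot rescale constant predictor {name} to [0, pi]")
    return (x - lo) * (math.pi / (hi - lo))


def assemble_design(
    data: pd.DataFrame | np.ndarray, spec: FourierSpec
) -> DesignMatrix:
    """Assemble the full n x L design by horizontally stacking predictor blocks.

    ``data`` holds the raw predictors, one column per predictor, in the order
    of ``spec.T``.
    """
    if isinstance(data, pd.DataFrame):
        names = tuple(str(c) for c in data.columns)
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = tuple(f"x{j}" for j in range(1, arr.shape[1] + 1))
    if arr.ndim != 2:
        raise SpecificationError(f"predictor table must be 2-d, got shape {arr.shape}")
    if arr.shape[1] != spec.p:
        raise SpecificationError(
            f"predictor table has {arr.shape[1]} columns but spec expects p={spec.p}"
        )

    blocks: list[np.ndarray] = []
    slices: list[slice] = []
    start = 0
    for j, Tj in enumerate(spec.T):
        x = _validate_predictor(arr[:, j], name=names[j])
        if spec.rescale:
            x = _rescale_to_pi(x, names[j])
        b = build_predictor_block(x, Tj)
        blocks.append(b)
        slices.append(slice(start, start + b.shape[1]))
        start += b.shape[1]

    values = np.hstack(blocks)
    rank = int(np.linalg.matrix_rank(values))
    return DesignMatrix(
        values=values,
        spec=spec,
        blocks=tuple(slices),
        labels=tuple(spec.labels()),
        rank=rank,
        predictor_names=names,
    )
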