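"""Synthetic data generation for the additive trend-plus-cosine model.

Responses follow y = X delta* + eps with eps ~ iid Normal(0, sigma^2), where
X is the Fourier design assembled from uniformly drawn predictors.  A single
integer seed drives predictors and noise through independent substreams, so
regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import FourierSpec, assemble_design
from .exceptions import SpecificationError

__all__ = ["SyntheticDataset", "generate_dataset", "generate_null_dataset"]

DEFAULT_RANGE = (0.0, 2.0 * np.pi)


@dataclass
class SyntheticDataset:
    """A generated dataset together with its ground truth."""

    predictors: pd.DataFrame  # n x p, columns x1..xp
    y: np.ndarray
    spec: FourierSpec
    delta_star: np.ndarray
    sigma2: float
    seed: int

    @property
    def n(self) -> int:
        return len(self.predictors)

    def to_frame(self, response: str = "y") -> pd.DataFrame:
        out = self.predictors.copy()
        out[response] = self.y
        return out

    def write(self, data_path, truth_path=None, response: str = "y") -> None:
        """Write the dataset as CSV plus a JSON sidecar recording the truth."""
        self.to_frame(response).to_csv(data_path, index=False)
        if truth_path is None:
            truth_path = Path(data_path).with_suffix(".truth.json")
        truth = {
            "T": list(self.spec.T),
            "rescale": self.spec.rescale,
            "delta_star": [float(v) for v in self.delta_star],
            "sigma2": float(self.sigma2),
            "seed": int(self.seed),
        }
        Path(truth_path).write_text(json.dumps(truth, indent=2) + "\n")


def generate_dataset(
    n: int,
    spec: FourierSpec,
    delta_star,
    sigma2: float,
    predictor_ranges=None,
    seed: int = 0,
) -> SyntheticDataset:
    """Draw predictors uniformly and responses from the additive cosine model.

    ``predictor_ranges`` is a list of p (low, high) intervals, default
    [0, 2*pi] for every predictor so the cosine harmonics are well excited.
    """
    n = int(n)
    if n < 1:
        raise SpecificationError(f"n must be >= 1, got {n}")
    delta_star = np.asarray(delta_star, dtype=float).ravel()
    if delta_star.size != spec.L:
        raise SpecificationError(
            f"delta_star has length {delta_star.size}, spec requires L={spec.L}"
        )
    if sigma2 < 0:
        raise SpecificationError(f"sigma2 must be >= 0, got {sigma2}")
    if predictor_ranges is None:
        predictor_ranges = [DEFAULT_RANGE] * spec.p
    if len(predictor_ranges) != spec.p:
        raise SpecificationError(
            f"need {spec.p} predictor ranges, got {len(predictor_ranges)}"
        )
    for lo, hi in predictor_ranges:
        if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
            raise SpecificationError(f"invalid predictor range ({lo}, {hi})")

    ss = np.random.SeedSequence(int(seed))
    pred_stream, noise_stream = (np.random.default_rng(s) for s in ss.spawn(2))

    cols = {}
    for j, (lo, hi) in enumerate(predictor_ranges, start=1):
        cols[f"x{j}"] = pred_stream.uniform(lo, hi, size=n)
    predictors = pd.DataFrame(cols)

    design = assemble_design(predictors, spec)
    signal = design.values @ delta_star
    noise = noise_stream.normal(0.0, np.sqrt(sigma2), size=n) if sigma2 > 0 else 0.0
    y = signal + noise
    return SyntheticDataset(
        predictors=predictors,
        y=np.asarray(y, dtype=float),
        spec=spec,
        delta_star=delta_star,
        sigma2=float(sigma2),
        seed=int(seed),
    )


def generate_null_dataset(
    n: int,
    spec: FourierSpec,
    null_indices,
    delta_star,
    sigma2: float,
    predictor_ranges=None,
    seed: int = 0,
) -> SyntheticDataset:
    """As :func:`generate_dataset`, asserting the stated coefficients are zero.

    Used for type-I-error studies: ``null_indices`` (0-based positions in
    delta_star) must already hold exact zeros.
    """
    delta_star = np.asarray(delta_star, dtype=float).ravel()
    null_indices = [int(i) for i in np.atleast_1d(null_indices)]
    for i in null_indices:
        if i < 0 or i >= delta_star.size:
            raise SpecificationError(f"null index {i} out of range")
        if delta_star[i] != 0.0:
            raise SpecificationError(
                f"delta_star[{i}] = {delta_star[i]} but is declared null"
            )
    return generate_dataset(
        n, spec, delta_star, sigma2, predictor_ranges=predictor_ranges, seed=seed
    )
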