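"""Synthetic design-response data with known ground truth.

Generators for both experiment types, so every pipeline stage can be
tested end to end without external data:

* ``simulate_pb`` — responses on a ±1 screening design as a sum of
  factor main effects plus i.i.d. Gaussian noise.  The coded slope is
  ``effect / 2`` so that the difference-of-means effect estimator
  recovers each stated effect exactly at zero noise.
* ``simulate_ccd`` — responses drawn from a known second-order
  polynomial in coded variables plus i.i.d. Gaussian noise; replicated
  centre points receive independent noise draws, giving the pure-error
  estimate something real to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designs import DesignMatrix, ResponseVector
from .rsm import expand_quadratic, quadratic_terms

__all__ = ["TruthSpec", "simulate_pb", "simulate_ccd"]


@dataclass
class TruthSpec:
    """Ground truth for a simulated experiment.

    ``pb_effects`` maps process-factor names to true main effects (in
    response units, on the difference-of-means scale); dummy columns are
    never listed — their true effect is zero by construction.
    ``ccd_coefficients`` maps quadratic model-term names (as produced by
    :func:`mediaopt.rsm.quadratic_terms`, plus ``"Intercept"``) to true
    coded-space coefficients.
    """

    noise_sd: float = 0.0
    seed: int = 0
    baseline: float = 0.0
    pb_effects: dict[str, float] = field(default_factory=dict)
    ccd_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_pb(design: DesignMatrix, truth: TruthSpec,
                rng: np.random.Generator | None = None) -> ResponseVector:
    """Simulate screening responses: ``y = baseline + sum(effect_j/2 * x_j) + eps``."""
    missing = [c for c in design.process_columns if c not in truth.pb_effects]
    if missing:
        raise ValueError(f"truth lists no effect for process factors {missing}")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    X = design.coded[design.process_columns].to_numpy(dtype=float)
    slopes = np.array([truth.pb_effects[c] / 2.0 for c in design.process_columns])
    y = truth.baseline + X @ slopes
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    return ResponseVector(values=y, run_ids=design.run_ids)


def simulate_ccd(design: DesignMatrix, truth: TruthSpec,
                 rng: np.random.Generator | None = None) -> ResponseVector:
    """Simulate second-order responses at the design's coded points."""
    names = design.process_columns
    required = ["Intercept"] + quadratic_terms(names)
    missing = [t for t in required if t not in truth.ccd_coefficients]
    if missing:
        raise ValueError(f"truth coefficient set incomplete; missing {missing}")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    X = expand_quadratic(design.coded[names].to_numpy(), names)
    beta = np.array([truth.ccd_coefficients[t] for t in X.columns])
    y = X.to_numpy() @ beta
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    return ResponseVector(values=y, run_ids=design.run_ids)
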