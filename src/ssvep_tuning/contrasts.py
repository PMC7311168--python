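"""Named hypothesis weight vectors over the six stimulus conditions.

Weights are given in the canonical condition order CS+, GS1, GS2, GS3, GS4,
CS-.  The lateral-inhibition shape is a difference of two Gaussians
(enhancement at CS+, suppression at the most similar morph); the quadratic
and linear shapes are the standard trend vectors used for generalization
gradients.  All vectors are centered to sum zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CONDITIONS

_WEIGHTS = {
    "lateral_inhibition": (2.0, -2.0, 0.5, 1.0, 0.5, -2.0),
    "quadratic": (2.5334, 1.0934, -0.0267, -0.8267, -1.3067, -1.4667),
    "linear": (2.5, 1.5, 0.5, -0.5, -1.5, -2.5),
}


@dataclass(frozen=True)
class ContrastWeights:
    name: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) != len(CONDITIONS):
            raise ValueError(f"expected {len(CONDITIONS)} weights, got {len(self.weights)}")
        if abs(sum(self.weights)) > 1e-6:
            raise ValueError("weights must be centered (sum zero)")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def unit(self) -> np.ndarray:
        """L2-normalized weights (model fit is invariant to this rescaling)."""
        w = self.as_array()
        return w / np.linalg.norm(w)

    def value_for(self, condition: str) -> float:
        return self.weights[CONDITIONS.index(condition)]


def contrast_weights(name: str) -> ContrastWeights:
    """Return the named centered weight vector; raises on unknown names."""
    try:
        raw = np.asarray(_WEIGHTS[name], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown contrast {name!r}; choose from {sorted(_WEIGHTS)}"
        ) from None
    centered = raw - raw.mean()
    return ContrastWeights(name, tuple(float(v) for v in centered))


def available_contrasts() -> tuple[str, ...]:
    return tuple(sorted(_WEIGHTS))
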