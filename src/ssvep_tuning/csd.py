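"""Current-source-density (surface Laplacian) transform of averaged epochs.

The scalp potential at each time sample is fitted with a regularized
spherical spline over the montage and the negative surface Laplacian of the
fit is returned at every sensor.  With the spline kernels used here a
degree-l spherical harmonic input maps to l(l+1) times itself (on the unit
sphere), so the output is in potential-per-squared-radius units; the whole
operation is linear and reference-free.

The regularization weight is added to the diagonal of the spline Gram
matrix *after* normalizing its trace, so the default weight 0.2 behaves
comparably across montage sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epochs import AveragedEpochs
from .montage import SensorMontage
from .spline import check_positions, cosine_distances, kernel_matrix


@dataclass
class CSDConfig:
    lambda_reg: float = 0.2
    m: int = 4
    legendre_terms: int = 50
    head_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.m < 2:
            raise ValueError("spline order m must be >= 2")
        if self.legendre_terms < 10:
            raise ValueError("need at least 10 Legendre terms")


def csd_matrix(positions: np.ndarray, config: CSDConfig | None = None) -> np.ndarray:
    """(n, n) linear operator applying the CSD transform to a potential vector."""
    config = config or CSDConfig()
    positions = check_positions(positions)
    n = positions.shape[0]
    if n < 4:
        raise ValueError("CSD requires at least 4 channels")
    cos = cosine_distances(positions, positions)
    g = kernel_matrix(cos, config.m, config.legendre_terms, laplacian=False)
    h = kernel_matrix(cos, config.m, config.legendre_terms, laplacian=True)
    scale = np.trace(g) / n
    gs = g / scale + config.lambda_reg * np.eye(n)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = gs
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    try:
        solver = np.linalg.inv(a)[:n, :n]  # maps y -> spline coefficients c
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient spline system") from exc
    return (h / scale) @ solver / config.head_radius**2


def csd_transform(
    avg: AveragedEpochs,
    montage: SensorMontage,
    config: CSDConfig | None = None,
) -> AveragedEpochs:
    """Apply the surface-Laplacian transform to every cell and time sample."""
    config = config or CSDConfig()
    if list(montage.labels) != list(avg.channels):
        raise ValueError("montage channels do not match averaged epochs")
    t = csd_matrix(montage.positions, config)
    out = np.einsum("ij,cjs->cis", t, avg.data)
    return replace(avg, data=out, units="CSD")
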