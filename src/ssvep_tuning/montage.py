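"""Sensor montages on the unit sphere with an occipital pooling cluster.

Synthetic montages place channels on a Fibonacci lattice; real electrode
positions can be loaded from a BESA-style ``.sfp`` file (``label x y z`` per
line).  The occipital cluster is the set of sensors nearest a designated
occipital pole direction, mirroring the 8-sensor pooling used for the 12 Hz
response.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Direction of the occipital pole in the montage coordinate frame
#: (x right, y anterior, z superior): posterior and slightly inferior.
OCCIPITAL_POLE = np.array([0.0, -0.9701425, -0.2425356])


@dataclass
class SensorMontage:
    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), unit norm
    occipital_cluster: tuple[str, ...]
    reference: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must have unit radius")
        missing = set(self.occipital_cluster) - set(self.labels)
        if missing:
            raise ValueError(f"cluster channels not in montage: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def cluster_indices(self) -> np.ndarray:
        return np.array([self.index(c) for c in self.occipital_cluster])


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_montage(
    n_channels: int = 129,
    cluster_size: int = 8,
    seed: int | None = None,
    pole: np.ndarray | None = None,
) -> SensorMontage:
    """Quasi-uniform synthetic montage with ``cluster_size`` occipital sensors.

    A seed applies a random rigid rotation to the lattice; the cluster is
    recomputed afterwards so all invariants hold for any seed.
    """
    if cluster_size >= n_channels:
        raise ValueError("cluster_size must be < n_channels")
    pos = _fibonacci_sphere(n_channels)
    if seed is not None:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        pos = pos @ q.T
    pole_v = OCCIPITAL_POLE if pole is None else np.asarray(pole, float)
    pole_v = pole_v / np.linalg.norm(pole_v)
    labels = [f"E{i + 1}" for i in range(n_channels)]
    order = np.argsort(-pos @ pole_v)  # descending cosine similarity
    cluster = tuple(labels[i] for i in sorted(order[:cluster_size]))
    reference = labels[int(np.argmax(pos[:, 2]))]  # vertex-most sensor
    return SensorMontage(labels, pos, cluster, reference)


def read_sfp(path: str | Path, cluster_size: int = 8,
             pole: np.ndarray | None = None) -> SensorMontage:
    """Load electrode positions from an sfp file; positions are re-normalized."""
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 'label x y z'")
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric coordinate") from exc
        labels.append(parts[0])
        rows.append(xyz)
    if not labels:
        raise ValueError(f"{path}: no electrode rows")
    pos = np.asarray(rows, float)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{path}: zero-length position vector")
    pos = pos / norms[:, None]
    pole_v = OCCIPITAL_POLE if pole is None else np.asarray(pole, float)
    pole_v = pole_v / np.linalg.norm(pole_v)
    order = np.argsort(-pos @ pole_v)
    cluster = tuple(labels[i] for i in sorted(order[:cluster_size]))
    reference = labels[int(np.argmax(pos[:, 2]))]
    return SensorMontage(labels, pos, cluster, reference)


def write_sfp(montage: SensorMontage, path: str | Path) -> None:
    lines = [
        f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
        for lab, (x, y, z) in zip(montage.labels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
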