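"""Synthetic subject profiles: anxiety covariate and ground-truth tuning gain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SpaiParams:
    """Truncated-normal parameters of the social-anxiety questionnaire score."""

    mean: float = 67.70
    sd: float = 19.74
    lower: float = 0.0
    upper: float = 200.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("spai sd must be > 0")
        if self.lower >= self.upper:
            raise ValueError("truncation bounds must satisfy lower < upper")


@dataclass
class AccentuationParams:
    """Linear link from the standardized covariate to the planted pattern gain.

    accentuation = gamma0 + gamma1 * z(spai) + N(0, noise_sd^2)
    where z() standardizes with the *configured* (population) mean and sd.
    """

    gamma0: float = 0.5
    gamma1: float = 0.3
    noise_sd: float = 0.15


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    spai: float
    accentuation: float
    cs_assignment: int  # 0 or 1: which of the two faces plays CS+


def sample_subjects(
    n: int,
    spai_params: SpaiParams | None = None,
    accentuation_params: AccentuationParams | None = None,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Draw ``n`` subjects with counterbalanced face-to-CS+ assignment."""
    if n < 0:
        raise ValueError("n must be >= 0")
    sp = spai_params or SpaiParams()
    ap = accentuation_params or AccentuationParams()
    rng = np.random.default_rng(seed)
    a = (sp.lower - sp.mean) / sp.sd
    b = (sp.upper - sp.mean) / sp.sd
    spai = stats.truncnorm.rvs(a, b, loc=sp.mean, scale=sp.sd, size=n, random_state=rng)
    z = (spai - sp.mean) / sp.sd
    accent = ap.gamma0 + ap.gamma1 * z + rng.normal(0.0, ap.noise_sd, size=n)
    if not np.all(np.isfinite(accent)):
        raise ValueError("non-finite accentuation")
    return [
        SubjectProfile(
            subject_id=f"S{i + 1:03d}",
            spai=float(spai[i]),
            accentuation=float(accent[i]),
            cs_assignment=i % 2,  # alternate: counts differ by at most 1
        )
        for i in range(n)
    ]
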