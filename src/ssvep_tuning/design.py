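"""Experiment schedules for a three-phase differential conditioning design.

The default design has a habituation and an acquisition phase with two face
conditions (CS+, CS-) and a generalization phase that adds four morphs
(GS1..GS4) ordered by similarity to the CS+.  Presentation order within each
phase is pseudo-randomized so that no condition appears more than twice in a
row, and only CS+ trials can be reinforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical condition order: threat face, morphs by decreasing similarity, safety face.
CONDITIONS = ("CS+", "GS1", "GS2", "GS3", "GS4", "CS-")

PHASES = ("habituation", "acquisition", "generalization")

_TWO_COND = ("CS+", "CS-")


class SchedulingError(RuntimeError):
    """Raised when no pseudo-random order satisfying the run-length constraint is found."""


@dataclass(frozen=True)
class Trial:
    phase: str
    condition: str
    reinforced: bool
    iti_ms: int


@dataclass
class PhaseSpec:
    """One experimental phase: which conditions appear, how often, reinforcement."""

    name: str
    conditions: tuple[str, ...]
    n_per_condition: int = 15
    reinforcement_fraction: float = 0.0  # applies to CS+ trials only

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if not 0.0 <= self.reinforcement_fraction <= 1.0:
            raise ValueError("reinforcement_fraction must be in [0, 1]")


@dataclass
class ScheduleConfig:
    phases: list[PhaseSpec] = field(default_factory=lambda: default_phases())
    iti_range_ms: tuple[int, int] = (2000, 2500)
    max_run: int = 2
    max_attempts: int = 10_000


def default_phases() -> list[PhaseSpec]:
    """The published design: 30 + 30 + 90 trials, 80%/40% CS+ reinforcement."""
    return [
        PhaseSpec("habituation", _TWO_COND, 15, 0.0),
        PhaseSpec("acquisition", _TWO_COND, 15, 0.8),
        PhaseSpec("generalization", CONDITIONS, 15, 0.4),
    ]


@dataclass
class ExperimentSchedule:
    trials: list[Trial]

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.trials)),
                "phase": [t.phase for t in self.trials],
                "condition": [t.condition for t in self.trials],
                "reinforced": [t.reinforced for t in self.trials],
                "iti_ms": [t.iti_ms for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentSchedule":
        return cls(
            [
                Trial(str(r.phase), str(r.condition), bool(r.reinforced), int(r.iti_ms))
                for r in df.itertuples()
            ]
        )

    def count(self, phase: str | None = None, condition: str | None = None,
              reinforced: bool | None = None) -> int:
        n = 0
        for t in self.trials:
            if phase is not None and t.phase != phase:
                continue
            if condition is not None and t.condition != condition:
                continue
            if reinforced is not None and t.reinforced != reinforced:
                continue
            n += 1
        return n


def _feasible(counts: dict[str, int], max_run: int) -> bool:
    # A condition with k trials needs at least k - 1 separators per extra run;
    # with run length <= max_run the other conditions must supply enough gaps:
    # ceil(k / max_run) - 1 <= sum(others).
    total = sum(counts.values())
    for cond, k in counts.items():
        others = total - k
        runs_needed = -(-k // max_run)  # ceil
        if runs_needed - 1 > others:
            return False
    return True


def _order_phase(conditions: tuple[str, ...], n_per: int, max_run: int,
                 max_attempts: int, rng: np.random.Generator) -> list[str]:
    pool = [c for c in conditions for _ in range(n_per)]
    arr = np.array(pool, dtype=object)
    for _ in range(max_attempts):
        rng.shuffle(arr)
        ok = True
        run = 1
        for i in range(1, len(arr)):
            run = run + 1 if arr[i] == arr[i - 1] else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return list(arr)
    raise SchedulingError(
        f"no order with runs <= {max_run} found in {max_attempts} attempts"
    )


def make_schedule(config: ScheduleConfig | None = None, seed: int = 0) -> ExperimentSchedule:
    """Generate a pseudo-randomized schedule.

    Reproducible for a fixed seed.  Raises :class:`SchedulingError` when the
    run-length constraint is provably infeasible or rejection sampling fails.
    """
    config = config or ScheduleConfig()
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    lo, hi = config.iti_range_ms
    for spec in config.phases:
        counts = {c: spec.n_per_condition for c in spec.conditions}
        if not _feasible(counts, config.max_run):
            raise SchedulingError(
                f"phase {spec.name!r}: run-length constraint infeasible for {counts}"
            )
        order = _order_phase(
            tuple(spec.conditions), spec.n_per_condition, config.max_run,
            config.max_attempts, rng,
        )
        n_reinf = int(round(spec.reinforcement_fraction * spec.n_per_condition))
        cs_positions = [i for i, c in enumerate(order) if c == "CS+"]
        reinforced_idx: set[int] = set()
        if n_reinf and cs_positions:
            chosen = rng.choice(len(cs_positions), size=min(n_reinf, len(cs_positions)),
                                replace=False)
            reinforced_idx = {cs_positions[i] for i in chosen}
        for i, cond in enumerate(order):
            trials.append(
                Trial(
                    phase=spec.name,
                    condition=cond,
                    reinforced=i in reinforced_idx,
                    iti_ms=int(rng.integers(lo, hi + 1)),
                )
            )
    return ExperimentSchedule(trials)
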