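"""Trial-schedule construction for repeated nest-defence assays.

The sampling design places up to five predator-presentation trials per
breeding female across the nesting cycle: three during incubation (days 2,
5 and 9 of incubation) and two during the early nestling stage (nestling
days 2 and 5).  Days are expressed relative to hatching (hatching day = 0);
with a 12-day incubation period the full schedule in centred days is
(-10, -7, -3, +2, +5).

The reference field design comprises 104 females and 448 trials, with a
per-female trial-count distribution of {5: 48, 4: 45, 3: 8, 2: 1, 1: 2}
caused by premature nest failure and females absent at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INCUBATION_LENGTH_DAYS = 12

#: Full per-female schedule in days centred on hatching (hatching day = 0).
FULL_SCHEDULE: tuple[int, ...] = (-10, -7, -3, 2, 5)
ALLOWED_DAYS = frozenset(FULL_SCHEDULE)

#: Reference per-female trial-count distribution of the field design
#: ({n_trials: n_females}); selected with ``pattern="paper"``.
REFERENCE_TRIAL_COUNTS: dict[int, int] = {5: 48, 4: 45, 3: 8, 2: 1, 1: 2}
REFERENCE_N_FEMALES = 104
REFERENCE_N_TRIALS = 448

STAGE_INCUBATION = "incubation"
STAGE_NESTLING = "nestling"


class DesignError(ValueError):
    """Invalid trial-design configuration."""


def stage_of(day_centred: float) -> str:
    """Breeding stage implied by a centred day (negative = incubation)."""
    return STAGE_INCUBATION if day_centred < 0 else STAGE_NESTLING


@dataclass(frozen=True)
class TrialDesign:
    """A mapping of female identifiers to their scheduled trial days.

    Days are centred on hatching; each female must have at least one trial
    and all days must belong to the five-point assay schedule.
    """

    schedule: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.schedule:
            raise DesignError("design must contain at least one female")
        for fem, days in self.schedule.items():
            if len(days) == 0:
                raise DesignError(f"female {fem!r} has no scheduled trials")
            bad = set(days) - ALLOWED_DAYS
            if bad:
                raise DesignError(
                    f"female {fem!r} has days {sorted(bad)} outside the "
                    f"assay schedule {sorted(ALLOWED_DAYS)}"
                )

    @property
    def females(self) -> list[str]:
        return list(self.schedule)

    @property
    def n_females(self) -> int:
        return len(self.schedule)

    @property
    def n_trials(self) -> int:
        return sum(len(d) for d in self.schedule.values())

    def trial_count_histogram(self) -> dict[int, int]:
        """{number of trials: number of females with that many trials}."""
        hist: dict[int, int] = {}
        for days in self.schedule.values():
            hist[len(days)] = hist.get(len(days), 0) + 1
        return hist

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per scheduled trial."""
        rows = [
            (fem, day, stage_of(day))
            for fem, days in self.schedule.items()
            for day in days
        ]
        return pd.DataFrame(rows, columns=["female_id", "day_centred", "stage"])


def _female_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"F{i + 1:0{width}d}" for i in range(n)]


def build_design(
    n_females: int,
    pattern: str | dict = "paper",
    seed: int | None = None,
) -> TrialDesign:
    """Build a trial design.

    Parameters
    ----------
    n_females
        Number of breeding females.
    pattern
        ``"paper"`` assigns the reference trial-count distribution
        {5: 48, 4: 45, 3: 8, 2: 1, 1: 2}; a females beyond those covered by
        the histogram receive the full five-trial schedule.  Alternatively a
        histogram ``{n_trials: n_females}`` or an explicit mapping
        ``{female_id: [days]}`` may be given.
    seed
        If given, the trial-count assignment is shuffled over females;
        otherwise counts are assigned in identifier order.

    Females with fewer than five trials keep the earliest part of the
    schedule (later trials are the ones lost to nest failure or absence).
    """
    if n_females < 1:
        raise DesignError("n_females must be >= 1")

    if isinstance(pattern, dict) and pattern and not all(
        isinstance(k, int) for k in pattern
    ):
        # explicit mapping female -> days
        schedule = {str(k): tuple(int(d) for d in v) for k, v in pattern.items()}
        return TrialDesign(schedule)

    if pattern == "paper":
        counts = dict(REFERENCE_TRIAL_COUNTS)
    elif isinstance(pattern, dict):
        counts = {int(k): int(v) for k, v in pattern.items()}
    else:
        raise DesignError(f"unknown pattern {pattern!r}")

    total = sum(counts.values())
    if total > n_females:
        raise DesignError(
            f"pattern assigns trials to {total} females but only "
            f"{n_females} are available"
        )
    for k in counts:
        if not 1 <= k <= len(FULL_SCHEDULE):
            raise DesignError(f"per-female trial count {k} outside 1..5")

    per_female = []
    for k, nf in sorted(counts.items(), reverse=True):
        per_female.extend([k] * nf)
    # any females not covered by the histogram get the full schedule
    per_female.extend([len(FULL_SCHEDULE)] * (n_females - total))

    if seed is not None:
        rng = np.random.default_rng(seed)
        per_female = list(rng.permutation(per_female))

    females = _female_ids(n_females)
    schedule = {
        fem: FULL_SCHEDULE[:k] for fem, k in zip(females, per_female)
    }
    return TrialDesign(schedule)
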