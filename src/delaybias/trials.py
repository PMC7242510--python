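"""Trial-level choice data: the ChoiceTrial container and its CSV dialect.

A trial pairs a smaller-sooner (SS) and a larger-later (LL) prospect with the
recorded response. The ``condition`` distinguishes trials whose SS option is
available today (``NOW``) from trials where both options are in the future
(``LATER``). Trial tables are exchanged as plain CSV with the columns

    participant_id, ss_amount, ss_delay_days, ll_amount, ll_delay_days,
    condition, choice

where ``choice`` is SS, LL or MISSING (no response within the deadline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .models import Prospect

__all__ = [
    "CHOICES",
    "CONDITIONS",
    "TRIAL_COLUMNS",
    "ChoiceTrial",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_csv",
    "read_trials_csv",
]

CHOICES = ("SS", "LL", "MISSING")
CONDITIONS = ("NOW", "LATER")

TRIAL_COLUMNS = [
    "participant_id",
    "ss_amount",
    "ss_delay_days",
    "ll_amount",
    "ll_delay_days",
    "condition",
    "choice",
]


@dataclass(frozen=True)
class ChoiceTrial:
    """One binary intertemporal choice; ``chosen`` may be None for a design
    that has not been administered yet."""

    ss: Prospect
    ll: Prospect
    chosen: Optional[str] = None
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.ss.amount < self.ll.amount:
            raise ValueError(
                f"ss.amount must be < ll.amount ({self.ss.amount} >= {self.ll.amount})"
            )
        if not self.ss.delay < self.ll.delay:
            raise ValueError(
                f"ss.delay must be < ll.delay ({self.ss.delay} >= {self.ll.delay})"
            )
        if self.chosen is not None and self.chosen not in CHOICES:
            raise ValueError(f"chosen must be one of {CHOICES}, got {self.chosen!r}")
        expected = "NOW" if self.ss.delay == 0 else "LATER"
        if self.condition == "":
            object.__setattr__(self, "condition", expected)
        elif self.condition != expected:
            raise ValueError(
                f"condition {self.condition!r} inconsistent with ss.delay={self.ss.delay}"
            )

    def with_choice(self, chosen: str) -> "ChoiceTrial":
        return ChoiceTrial(self.ss, self.ll, chosen, self.condition)


def trials_to_frame(trials: Iterable[ChoiceTrial], participant_id: str) -> pd.DataFrame:
    rows = [
        {
            "participant_id": participant_id,
            "ss_amount": t.ss.amount,
            "ss_delay_days": t.ss.delay,
            "ll_amount": t.ll.amount,
            "ll_delay_days": t.ll.delay,
            "condition": t.condition,
            "choice": t.chosen if t.chosen is not None else "MISSING",
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> dict[str, list[ChoiceTrial]]:
    """Group a trial table by participant and rebuild ChoiceTrial objects."""
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    out: dict[str, list[ChoiceTrial]] = {}
    for pid, sub in frame.groupby("participant_id", sort=False):
        out[str(pid)] = [
            ChoiceTrial(
                Prospect(float(r.ss_amount), float(r.ss_delay_days)),
                Prospect(float(r.ll_amount), float(r.ll_delay_days)),
                str(r.choice),
                str(r.condition),
            )
            for r in sub.itertuples(index=False)
        ]
    return out


def write_trials_csv(path, trials_by_participant: dict[str, list[ChoiceTrial]]) -> None:
    frames = [
        trials_to_frame(trials, pid) for pid, trials in trials_by_participant.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path) -> dict[str, list[ChoiceTrial]]:
    return frame_to_trials(pd.read_csv(path))
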