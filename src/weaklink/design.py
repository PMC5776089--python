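"""Block-design paradigm: alternating rest and task periods.

The default session is nine 30 s rest / 30 s task cycles followed by one
closing 30 s rest period — 570 s, i.e. 190 volumes at TR 3 s.  Each task
period carries one of the three condition tags; by default the conditions
are interleaved A,B,C and the cycle repeats three times, so every condition
occurs in exactly three task periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = ["CONDITIONS", "REST", "Period", "DesignParadigm", "make_design"]

REST = "rest"
CONDITIONS = ("Task", "Task+AgonistStim", "Task+ControlStim")


class Period(NamedTuple):
    label: str  # "rest" or "task"
    duration_s: float
    condition: str  # one of CONDITIONS for task periods, "none" for rest


@dataclass(frozen=True)
class DesignParadigm:
    """Ordered rest/task periods sampled at a fixed TR."""

    tr_s: float
    periods: tuple[Period, ...]
    total_volumes: int = field(default=0)

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for p in self.periods:
            n, rem = divmod(p.duration_s, self.tr_s)
            if p.duration_s <= 0 or abs(rem) > 1e-9 and abs(rem - self.tr_s) > 1e-9:
                raise ValueError(
                    f"period {p}: duration must be a positive integer multiple "
                    f"of TR={self.tr_s}"
                )
        total = int(round(sum(p.duration_s for p in self.periods) / self.tr_s))
        if self.total_volumes == 0:
            object.__setattr__(self, "total_volumes", total)
        elif self.total_volumes != total:
            raise ValueError(
                f"total_volumes={self.total_volumes} inconsistent with periods ({total})"
            )

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.periods)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in self.periods:
            if p.label == "task" and p.condition not in seen:
                seen.append(p.condition)
        return tuple(seen)

    def volume_labels(self) -> np.ndarray:
        """Per-volume tag: the active condition during task periods, 'rest' otherwise."""
        labels: list[str] = []
        for p in self.periods:
            n = int(round(p.duration_s / self.tr_s))
            tag = p.condition if p.label == "task" else REST
            labels.extend([tag] * n)
        return np.asarray(labels, dtype=object)

    def task_blocks(self, condition: str) -> list[tuple[int, int]]:
        """(first volume index, n volumes) of every task period tagged `condition`."""
        blocks = []
        vol = 0
        for p in self.periods:
            n = int(round(p.duration_s / self.tr_s))
            if p.label == "task" and p.condition == condition:
                blocks.append((vol, n))
            vol += n
        return blocks

    def to_frame(self) -> pd.DataFrame:
        onset = 0.0
        rows = []
        for p in self.periods:
            rows.append(
                {"onset_s": onset, "duration_s": p.duration_s,
                 "label": p.label, "condition": p.condition}
            )
            onset += p.duration_s
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tr_s: float) -> "DesignParadigm":
        periods = tuple(
            Period(str(r.label), float(r.duration_s), str(r.condition))
            for r in df.itertuples()
        )
        return cls(tr_s=tr_s, periods=periods)


def make_design(
    n_cycles: int = 9,
    period_s: float = 30.0,
    tr_s: float = 3.0,
    condition_sequence: Sequence[str] | None = None,
) -> DesignParadigm:
    """Build the rest–task block paradigm.

    `n_cycles` rest–task cycles are followed by one closing rest period, so
    the default (9, 30, 3) yields 570 s and 190 volumes.  Task periods carry
    condition tags cycling through `condition_sequence` (default: the three
    conditions interleaved, each occurring n_cycles/3 times).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    n, rem = divmod(period_s, tr_s)
    if period_s <= 0 or (abs(rem) > 1e-9 and abs(rem - tr_s) > 1e-9):
        raise ValueError(
            f"period_s={period_s} must be a positive integer multiple of tr_s={tr_s}"
        )
    if condition_sequence is None:
        condition_sequence = [CONDITIONS[i % len(CONDITIONS)] for i in range(n_cycles)]
    elif len(condition_sequence) != n_cycles:
        raise ValueError("condition_sequence must name one condition per cycle")

    periods: list[Period] = []
    for i in range(n_cycles):
        periods.append(Period(REST, period_s, "none"))
        periods.append(Period("task", period_s, condition_sequence[i]))
    periods.append(Period(REST, period_s, "none"))  # closing rest
    return DesignParadigm(tr_s=tr_s, periods=tuple(periods))
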