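"""Fixed 68-trial schedule of the forward spatial-span task.

The task presents four 16-trial series; within each series set sizes are
blocked in groups of four in the order 6, 8, 5, 7.  Two very easy catch
trials (set size 3) are inserted between the first and second series and
between the third and fourth series, and a rest break follows the second
series (the halfway point).  Every participant sees the identical order, so
between-participant differences in the performance trajectory cannot be
driven by differences in difficulty history.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import pandas as pd

#: set sizes of one 16-trial series, blocked in fours
SERIES_SET_SIZES: tuple[int, ...] = (6,) * 4 + (8,) * 4 + (5,) * 4 + (7,) * 4
CATCH_SET_SIZE: int = 3
N_TRIALS: int = 68
#: main-task set sizes are centred at their mean before entering the model
SET_SIZE_CENTER: float = 6.5


@dataclass(frozen=True)
class ScheduleEntry:
    trial_index: int          # 1-based position in the full 68-trial sequence
    set_size: int
    is_catch: bool
    block_index: int          # 1..4; catch trials carry the preceding series' index
    break_after: bool


@dataclass(frozen=True)
class TrialSchedule:
    entries: tuple[ScheduleEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ScheduleEntry]:
        return iter(self.entries)

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a table with one row per trial."""
        return pd.DataFrame(
            {
                "trial_index": [e.trial_index for e in self.entries],
                "set_size": [e.set_size for e in self.entries],
                "is_catch": [e.is_catch for e in self.entries],
                "block_index": [e.block_index for e in self.entries],
                "break_after": [e.break_after for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def total_clicks(self) -> int:
        """Total responses a participant produces (one click per sequence item)."""
        return sum(e.set_size for e in self.entries)


def build_schedule() -> TrialSchedule:
    """Construct the fixed trial order: series 1, catch pair, series 2,
    break, series 3, catch pair, series 4.

    Deterministic; two calls return equal schedules.
    """
    entries: list[ScheduleEntry] = []
    index = 1

    def add_series(block: int) -> None:
        nonlocal index
        for size in SERIES_SET_SIZES:
            entries.append(ScheduleEntry(index, size, False, block, False))
            index += 1

    def add_catch_pair(block: int) -> None:
        nonlocal index
        for _ in range(2):
            entries.append(ScheduleEntry(index, CATCH_SET_SIZE, True, block, False))
            index += 1

    add_series(1)
    add_catch_pair(1)
    add_series(2)
    # rest break at the halfway point, after the second series
    last = entries[-1]
    entries[-1] = ScheduleEntry(last.trial_index, last.set_size, last.is_catch,
                                last.block_index, True)
    add_series(3)
    add_catch_pair(3)
    add_series(4)
    return TrialSchedule(tuple(entries))


def validate_schedule(schedule: TrialSchedule) -> list[str]:
    """Check every structural invariant; return one message per violation.

    An empty list means the schedule is exactly the task design.
    """
    violations: list[str] = []
    entries = list(schedule.entries)

    if len(entries) != N_TRIALS:
        violations.append(f"count: expected {N_TRIALS} trials, found {len(entries)}")
    if [e.trial_index for e in entries] != list(range(1, len(entries) + 1)):
        violations.append("indexing: trial_index is not contiguous 1-based")

    from collections import Counter

    counts = Counter(e.set_size for e in entries)
    for size in (5, 6, 7, 8):
        if counts.get(size, 0) != 16:
            violations.append(
                f"count: set size {size} appears {counts.get(size, 0)} times, expected 16"
            )
    if counts.get(CATCH_SET_SIZE, 0) != 4:
        violations.append(
            f"count: set size {CATCH_SET_SIZE} appears {counts.get(CATCH_SET_SIZE, 0)} "
            "times, expected 4"
        )
    if any(e.set_size == CATCH_SET_SIZE and not e.is_catch for e in entries):
        violations.append("catch flag: a set-size-3 trial is not flagged as catch")
    if any(e.is_catch and e.set_size != CATCH_SET_SIZE for e in entries):
        violations.append("catch flag: a catch trial does not have set size 3")

    # runs of identical set sizes among main trials must have length exactly 4
    main = [e for e in entries if not e.is_catch]
    run_len = 0
    prev_size = None
    for e in main + [None]:  # sentinel flushes the last run
        size = e.set_size if e is not None else None
        if size == prev_size:
            run_len += 1
        else:
            if prev_size is not None and run_len != 4:
                violations.append(
                    f"block length: run of set size {prev_size} has length {run_len}, "
                    "expected 4"
                )
            prev_size, run_len = size, 1

    # within each series the block order is 6, 8, 5, 7
    if len(main) == 64:
        for series in range(4):
            sizes = tuple(e.set_size for e in main[series * 16:(series + 1) * 16])
            if sizes != SERIES_SET_SIZES:
                violations.append(
                    f"series order: series {series + 1} does not follow the "
                    "6,8,5,7 blocked order"
                )

    # catch pairs sit between series 1/2 and 3/4, never inside a series
    catch_positions = [e.trial_index for e in entries if e.is_catch]
    if len(entries) == N_TRIALS and catch_positions != [17, 18, 51, 52]:
        violations.append(
            f"catch placement: catch trials at {catch_positions}, expected [17, 18, 51, 52]"
        )

    breaks = [e.trial_index for e in entries if e.break_after]
    if len(entries) == N_TRIALS and breaks != [34]:
        violations.append(f"break placement: break flags at {breaks}, expected [34]")

    return violations
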