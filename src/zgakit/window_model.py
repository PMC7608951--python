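"""Closed-form model of how cell-cycle duration limits productive
transcription.

Mitosis aborts every nascent transcript, so within one cycle a gene can
only finish transcripts during the *productive window*:

    transcriptional window = interphase - lag          (clamped at 0)
    eclipse time           = TU length (kb) * 0.7 min/kb
    productive window      = window - eclipse          (clamped at 0)

The time-averaged expression efficiency of a cycle is the productive
window divided by total cycle time (interphase + mitosis), in percent.
The terminal cycle (cycle 14 by default) is not followed by a mitosis, so
its efficiency is set to 100% regardless of TU length; this override can
be disabled for sensitivity analyses.
"""

from __future__ import annotations

import pandas as pd

from zgakit.schedule import CycleSchedule


def eclipse_time(tu_length_kb: float, schedule: CycleSchedule) -> float:
    """Minutes between initiation and production of a complete transcript.

    Proportional to primary-TU length: ``tu_length_kb *
    schedule.elongation_min_per_kb`` (0.7 min/kb by default).
    """
    if not (tu_length_kb >= 0):
        raise ValueError(f"TU length must be >= 0, got {tu_length_kb!r}")
    return tu_length_kb * schedule.elongation_min_per_kb


def transcription_window(cycle_index: int, schedule: CycleSchedule) -> float:
    """Minutes available to extend transcripts in a cycle:
    interphase minus the post-mitotic lag, clamped at zero."""
    return max(0.0, schedule.interphase_min(cycle_index) - schedule.lag_min)


def productive_window(
    cycle_index: int, tu_length_kb: float, schedule: CycleSchedule
) -> float:
    """Minutes during which *complete* transcripts can be produced:
    transcriptional window minus eclipse time, clamped at zero."""
    return max(
        0.0,
        transcription_window(cycle_index, schedule)
        - eclipse_time(tu_length_kb, schedule),
    )


def expression_efficiency(
    cycle_index: int,
    tu_length_kb: float,
    schedule: CycleSchedule,
    terminal_override: bool = True,
) -> float:
    """Time-averaged percent expression for one cycle and TU length.

    ``100 * productive_window / (interphase + mitosis)``, in [0, 100].
    The terminal cycle returns exactly 100 (no further mitosis aborts
    transcription) unless ``terminal_override`` is False.
    """
    if terminal_override and schedule.is_terminal(cycle_index):
        # touch the schedule so unknown cycles still raise
        schedule.interphase_min(cycle_index)
        if not (tu_length_kb >= 0):
            raise ValueError(f"TU length must be >= 0, got {tu_length_kb!r}")
        return 100.0
    total = schedule.interphase_min(cycle_index) + schedule.mitosis_min(cycle_index)
    return 100.0 * productive_window(cycle_index, tu_length_kb, schedule) / total


def earliest_expressible_cycle(
    tu_length_kb: float,
    schedule: CycleSchedule,
    include_terminal: bool = True,
) -> int | None:
    """Smallest cycle index whose productive window is positive.

    Each successive (longer) cycle is compatible with completion of longer
    primary transcripts, so the result is non-decreasing in TU length.
    The terminal cycle has unbounded interphase and therefore always
    qualifies when ``include_terminal`` is True; with it excluded, ``None``
    is returned when no pre-terminal window suffices.
    """
    for c in schedule.cycle_indices:
        if schedule.is_terminal(c):
            if include_terminal:
                return c
            continue
        if productive_window(c, tu_length_kb, schedule) > 0:
            return c
    return None


def efficiency_table(
    lengths_kb: list[float],
    schedule: CycleSchedule,
    terminal_override: bool = True,
) -> pd.DataFrame:
    """Percent expression efficiency by (TU length, cycle).

    Rows are TU lengths in kb, columns cycle indices. Longer TUs show a
    later and more abrupt onset of productive expression.
    """
    if not len(lengths_kb):
        raise ValueError("lengths_kb must be non-empty")
    rows = {
        float(length): [
            expression_efficiency(c, length, schedule, terminal_override)
            for c in schedule.cycle_indices
        ]
        for length in lengths_kb
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=schedule.cycle_indices)
    table.index.name = "tu_length_kb"
    table.columns.name = "cycle"
    return table
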