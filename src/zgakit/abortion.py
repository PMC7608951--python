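"""Event-level simulator of transcription initiation, elongation and
abortion at mitosis.

Initiation is a homogeneous Poisson process per nucleus over the
transcriptional window ``(lag, interphase]``. A transcript initiated at
time ``t`` (measured from the start of interphase) is completed iff
``t + eclipse <= interphase``; otherwise the next mitosis aborts it. The
expectation of the completed count is therefore exactly
``rate * nuclei * productive_window``, the closed form in
:mod:`zgakit.window_model`. In the terminal cycle no mitosis follows, so
nothing is aborted.

Per-cycle random streams are derived deterministically from one root seed,
so per-cycle results do not depend on the order cycles are simulated in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zgakit.schedule import CycleSchedule, TranscriptionUnit
from zgakit.window_model import (
    earliest_expressible_cycle,
    eclipse_time,
    productive_window,
    transcription_window,
)


@dataclass(frozen=True)
class SimParams:
    """Initiation rate (initiations/minute/nucleus), per-cycle nucleus
    counts, and the root seed for reproducibility."""

    initiation_rate: float
    n_nuclei_by_cycle: dict[int, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.initiation_rate >= 0 and np.isfinite(self.initiation_rate)):
            raise ValueError("initiation_rate must be finite and >= 0")
        for c, n in self.n_nuclei_by_cycle.items():
            if n < 1:
                raise ValueError(f"nucleus count must be >= 1 (cycle {c})")

    def nuclei(self, cycle_index: int) -> int:
        return int(self.n_nuclei_by_cycle.get(cycle_index, 1))


def expected_completed(
    cycle_index: int,
    tu: TranscriptionUnit,
    params: SimParams,
    schedule: CycleSchedule,
) -> float:
    """Expected number of completed transcripts in one cycle:
    ``rate * nuclei * productive_window`` (for the terminal cycle the full
    transcriptional window is productive — nothing is aborted)."""
    if schedule.is_terminal(cycle_index):
        window = transcription_window(cycle_index, schedule)
    else:
        window = productive_window(cycle_index, tu.tu_length_kb, schedule)
    return params.initiation_rate * params.nuclei(cycle_index) * window


def _cycle_rng(seed: int, cycle_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(cycle_index)]))


def simulate_completed(
    cycle_range: list[int],
    tu: TranscriptionUnit,
    params: SimParams,
    schedule: CycleSchedule,
) -> pd.DataFrame:
    """Simulate initiation events over the given cycles.

    Returns a DataFrame with columns ``cycle, initiated, completed,
    aborted`` (``initiated = completed + aborted`` always). Initiation
    times are drawn uniformly over ``(lag, interphase]`` with Poisson
    event counts; initiations that cannot finish before the interphase
    ends are counted as aborted.
    """
    ecl = eclipse_time(tu.tu_length_kb, schedule)
    rows = []
    for c in cycle_range:
        inter = schedule.interphase_min(c)
        window = transcription_window(c, schedule)
        rng = _cycle_rng(params.seed, c)
        mean_events = params.initiation_rate * params.nuclei(c) * window
        n_init = int(rng.poisson(mean_events)) if mean_events > 0 else 0
        if n_init:
            start = rng.uniform(schedule.lag_min, inter, size=n_init)
            if schedule.is_terminal(c):
                completed = n_init
            else:
                completed = int(np.count_nonzero(start + ecl <= inter))
        else:
            completed = 0
        rows.append(
            {
                "cycle": c,
                "initiated": n_init,
                "completed": completed,
                "aborted": n_init - completed,
            }
        )
    return pd.DataFrame(rows, columns=["cycle", "initiated", "completed", "aborted"])


def onset_profile(
    tu: TranscriptionUnit, params: SimParams, schedule: CycleSchedule
) -> int | None:
    """First cycle with nonzero expected completed transcripts.

    Contractually equal to
    :func:`zgakit.window_model.earliest_expressible_cycle` whenever the
    initiation rate is positive.
    """
    if params.initiation_rate == 0:
        return None
    return earliest_expressible_cycle(tu.tu_length_kb, schedule)
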