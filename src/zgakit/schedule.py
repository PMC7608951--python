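"""Cell-cycle schedules for the pre-MBT cleavage divisions.

Pre-MBT cycles are simple alternations of S phase and mitosis (no gap
phases), so interphase duration is equated with S-phase duration. The
schedule also carries the two global kinetic parameters of the
transcription model: the post-mitotic lag before initiation resumes and
the elongation cost per kilobase of primary transcription unit.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

#: minutes between the end of mitosis and resumption of initiation
DEFAULT_LAG_MIN = 4.0
#: elongation cost, minutes per kilobase of primary TU
DEFAULT_ELONGATION_MIN_PER_KB = 0.7
#: mitosis duration, minutes
DEFAULT_MITOSIS_MIN = 5.0
#: cycle whose interphase is treated as unbounded (cellularization stage)
DEFAULT_TERMINAL_CYCLE = 14


@dataclass(frozen=True)
class TranscriptionUnit:
    """A gene's primary transcription unit (TU)."""

    gene_id: str
    tu_length_kb: float

    def __post_init__(self) -> None:
        if not (self.tu_length_kb >= 0):  # also rejects NaN
            raise ValueError(
                f"TU length must be finite and non-negative, got "
                f"{self.tu_length_kb!r} for {self.gene_id!r}"
            )


@dataclass(frozen=True)
class CycleSchedule:
    """Per-cycle interphase/mitosis durations plus global model parameters.

    Parameters
    ----------
    cycles
        Ordered ``(cycle_index, interphase_min, mitosis_min)`` triples with
        strictly increasing cycle indices.
    lag_min
        Post-mitotic lag before transcription initiation, minutes.
    elongation_min_per_kb
        Polymerase traversal time per kb of primary TU, minutes/kb.
    terminal_cycle
        Cycle treated as having an unbounded interphase: no further mitosis
        aborts transcripts, so expression efficiency is 100% there.
    """

    cycles: tuple[tuple[int, float, float], ...]
    lag_min: float = DEFAULT_LAG_MIN
    elongation_min_per_kb: float = DEFAULT_ELONGATION_MIN_PER_KB
    terminal_cycle: int = DEFAULT_TERMINAL_CYCLE
    _by_cycle: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("schedule must contain at least one cycle")
        if self.lag_min < 0:
            raise ValueError("lag_min must be >= 0")
        if not (self.elongation_min_per_kb > 0):
            raise ValueError("elongation_min_per_kb must be > 0")
        idx = [c for c, _, _ in self.cycles]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("cycle indices must be strictly increasing")
        by = {}
        for c, inter, mito in self.cycles:
            if not (inter > 0):
                raise ValueError(f"interphase must be > 0 for cycle {c}")
            if mito < 0:
                raise ValueError(f"mitosis must be >= 0 for cycle {c}")
            by[int(c)] = (float(inter), float(mito))
        object.__setattr__(self, "_by_cycle", by)

    @property
    def cycle_indices(self) -> list[int]:
        return [c for c, _, _ in self.cycles]

    def interphase_min(self, cycle_index: int) -> float:
        try:
            return self._by_cycle[cycle_index][0]
        except KeyError:
            raise KeyError(f"cycle {cycle_index} not in schedule") from None

    def mitosis_min(self, cycle_index: int) -> float:
        try:
            return self._by_cycle[cycle_index][1]
        except KeyError:
            raise KeyError(f"cycle {cycle_index} not in schedule") from None

    def is_terminal(self, cycle_index: int) -> bool:
        return cycle_index == self.terminal_cycle

    def shifted_slowing(self, n_cycles: int = 1) -> "CycleSchedule":
        """Schedule with the cycle-slowing program delayed by ``n_cycles``.

        Emulates haploid embryos, whose interphase lengthening happens one
        cycle later than in diploids: cycle ``c`` receives the interphase
        the unshifted schedule assigns to cycle ``c - n_cycles``. Cycles
        with no donor keep the earliest (shortest) interphase.
        """
        first = self.cycles[0]
        new = []
        for c, _, mito in self.cycles:
            donor = c - n_cycles
            inter = self._by_cycle.get(donor, (first[1], first[2]))[0]
            new.append((c, inter, mito))
        return CycleSchedule(
            cycles=tuple(new),
            lag_min=self.lag_min,
            elongation_min_per_kb=self.elongation_min_per_kb,
            terminal_cycle=self.terminal_cycle,
        )


def load_schedule(
    schedule_tsv: str | Path,
    params_yaml: str | Path | None = None,
) -> CycleSchedule:
    """Read a schedule from a TSV (columns: cycle, interphase_min,
    mitosis_min) plus optional YAML with keys lag_min,
    elongation_min_per_kb, terminal_cycle."""
    df = pd.read_csv(schedule_tsv, sep="\t")
    required = {"cycle", "interphase_min", "mitosis_min"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    kwargs = {}
    if params_yaml is not None:
        with open(params_yaml) as fh:
            params = yaml.safe_load(fh) or {}
        allowed = {"lag_min", "elongation_min_per_kb", "terminal_cycle"}
        bad = set(params) - allowed
        if bad:
            raise ValueError(f"unknown schedule parameters: {sorted(bad)}")
        kwargs.update(params)
    cycles = tuple(
        (int(r.cycle), float(r.interphase_min), float(r.mitosis_min))
        for r in df.itertuples()
    )
    return CycleSchedule(cycles=cycles, **kwargs)


def default_schedule() -> CycleSchedule:
    """The shipped cycle 8-14 schedule.

    Interphase anchors are measured S-phase durations (7 min at cycle 10,
    15 min at cycle 13); cycle 8 is set so its transcriptional window is
    12 s; the unprinted cycles 9, 11, 12 are reconstructed as a monotone
    interpolation and can be overridden via ``load_schedule``.
    """
    path = importlib.resources.files("zgakit.data") / "default_schedule.tsv"
    return load_schedule(str(path))
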