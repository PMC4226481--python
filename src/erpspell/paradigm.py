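"""Stimulus schedules for the three matrix spellers (RC, RASP, RASP-F).

A speller presents a 6x6 matrix of 36 symbols (A-Z, 1-9, underscore).
One *sequence* is a block of 12 flashes in which every symbol flashes
exactly twice; spelling one letter (one *trial*) consists of a countdown
followed by a fixed number of sequences.

Conditions
----------
RC
    The classic row-column paradigm: the 6 physical rows and 6 physical
    columns of the on-screen matrix flash once each, in random order.
RASP
    Random set presentation: before each sequence the 36 symbols are
    shuffled into a fresh *virtual* 6x6 matrix; the 12 flash sets are
    that matrix's rows and columns in random interleaved order, so
    on-screen neighbours of the target rarely co-flash with it.
RASP_F
    RASP with face overlays: virtual rows flash with the user's own
    (self) face, virtual columns with other (non-self) faces, giving a
    50:50 self/non-self split within every sequence.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("RC", "RASP", "RASP_F")

STIM_HIGHLIGHT = "highlight"
STIM_SELF_FACE = "self_face"
STIM_NON_SELF_FACE = "non_self_face"

N_ROWS = 6
N_COLS = 6
FLASHES_PER_SEQUENCE = N_ROWS + N_COLS


@dataclass(frozen=True)
class LetterMatrix:
    """Bijection between 36 symbols and the cells of a 6x6 grid."""

    symbols: tuple[str, ...]
    layout: dict[str, tuple[int, int]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.symbols) != 36 or len(set(self.symbols)) != 36:
            raise ValueError("matrix must contain exactly 36 unique symbols")
        cells = set(self.layout.values())
        if len(cells) != 36 or set(self.layout) != set(self.symbols):
            raise ValueError("layout must be a bijection symbols <-> cells")

    def position(self, symbol: str) -> tuple[int, int]:
        try:
            return self.layout[symbol]
        except KeyError:
            raise KeyError(f"symbol {symbol!r} not in matrix") from None

    def row(self, r: int) -> frozenset[str]:
        return frozenset(s for s, (rr, _) in self.layout.items() if rr == r)

    def col(self, c: int) -> frozenset[str]:
        return frozenset(s for s, (_, cc) in self.layout.items() if cc == c)


@dataclass(frozen=True)
class TimingConfig:
    """Flash timing; onset spacing within a sequence is flash + ISI."""

    flash_duration: float = 0.135  # s
    isi: float = 0.050             # s
    countdown: float = 2.0         # s before every trial
    sequences_per_trial: int = 10

    def __post_init__(self) -> None:
        if min(self.flash_duration, self.isi, self.countdown) <= 0:
            raise ValueError("all durations must be positive")
        if self.sequences_per_trial < 1:
            raise ValueError("sequences_per_trial must be >= 1")

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony (flash duration + ISI), s."""
        return self.flash_duration + self.isi

    def trial_duration(self, n_sequences: int | None = None) -> float:
        """Countdown plus ``n_sequences`` full sequences, s."""
        n = self.sequences_per_trial if n_sequences is None else n_sequences
        return self.countdown + n * FLASHES_PER_SEQUENCE * self.soa


@dataclass(frozen=True)
class FlashEvent:
    onset: float                 # s from run start
    letters: frozenset[str]      # the 6 symbols flashed together
    stimulus_class: str
    trial_index: int
    sequence_index: int
    flash_index: int             # 0..11 within the sequence
    is_target: bool

    def __post_init__(self) -> None:
        if len(self.letters) != 6:
            raise ValueError("a flash set contains exactly 6 symbols")


@dataclass(frozen=True)
class StimulusSchedule:
    condition: str
    matrix: LetterMatrix
    targets: tuple[str, ...]
    events: tuple[FlashEvent, ...]
    timing: TimingConfig

    @property
    def n_trials(self) -> int:
        return len(self.targets)

    def trial_events(self, trial: int) -> list[FlashEvent]:
        return [e for e in self.events if e.trial_index == trial]

    def to_frame(self) -> pd.DataFrame:
        """Event log as a tidy table (one row per flash)."""
        rows = [
            {
                "onset_s": e.onset,
                "trial": e.trial_index,
                "sequence": e.sequence_index,
                "flash": e.flash_index,
                "letters": "".join(sorted(e.letters)),
                "stim_class": e.stimulus_class,
                "is_target": int(e.is_target),
            }
            for e in self.events
        ]
        return pd.DataFrame(rows)


def make_letter_matrix() -> LetterMatrix:
    """The standard on-screen matrix: A..Z, 1..9, _ filled row-major."""
    symbols = tuple(string.ascii_uppercase) + tuple("123456789") + ("_",)
    layout = {s: divmod(i, N_COLS) for i, s in enumerate(symbols)}
    return LetterMatrix(symbols=symbols, layout=layout)


def schedule_sequence(condition: str, matrix: LetterMatrix,
                      rng: np.random.Generator,
                      ) -> list[tuple[frozenset[str], str]]:
    """Draw the 12 flash sets of one sequence.

    Returns an ordered list of ``(letter_set, stimulus_class)`` pairs.
    Every symbol appears in exactly two of the 12 sets in every condition.
    """
    if condition == "RC":
        sets = [(matrix.row(r), STIM_HIGHLIGHT) for r in range(N_ROWS)]
        sets += [(matrix.col(c), STIM_HIGHLIGHT) for c in range(N_COLS)]
        order = rng.permutation(FLASHES_PER_SEQUENCE)
        return [sets[i] for i in order]
    if condition in ("RASP", "RASP_F"):
        virtual = rng.permutation(np.array(matrix.symbols)).reshape(N_ROWS, N_COLS)
        row_class = STIM_SELF_FACE if condition == "RASP_F" else STIM_HIGHLIGHT
        col_class = STIM_NON_SELF_FACE if condition == "RASP_F" else STIM_HIGHLIGHT
        sets = [(frozenset(virtual[r, :]), row_class) for r in range(N_ROWS)]
        sets += [(frozenset(virtual[:, c]), col_class) for c in range(N_COLS)]
        order = rng.permutation(FLASHES_PER_SEQUENCE)
        return [sets[i] for i in order]
    raise ValueError(f"unknown condition {condition!r}")


def build_schedule(condition: str, targets: Iterable[str],
                   timing: TimingConfig | None = None,
                   rng: np.random.Generator | int | None = None,
                   matrix: LetterMatrix | None = None) -> StimulusSchedule:
    """Build the full flash schedule for copy-spelling ``targets``.

    Each trial starts with a countdown, then ``timing.sequences_per_trial``
    sequences of 12 flashes at a fixed onset spacing of flash + ISI.
    """
    timing = timing or TimingConfig()
    matrix = matrix or make_letter_matrix()
    rng = np.random.default_rng(rng)
    targets = tuple(targets)
    missing = [t for t in targets if t not in matrix.layout]
    if missing:
        raise ValueError(f"target symbols not in matrix: {missing}")

    events: list[FlashEvent] = []
    # exact decimal bookkeeping: onsets accumulate in integer
    # microseconds, so they survive a 6-decimal event-log round trip
    t_us = 0
    countdown_us = round(timing.countdown * 1e6)
    soa_us = round(timing.soa * 1e6)
    for trial, target in enumerate(targets):
        t_us += countdown_us
        for seq in range(timing.sequences_per_trial):
            for flash, (letters, stim_class) in enumerate(
                    schedule_sequence(condition, matrix, rng)):
                events.append(FlashEvent(
                    onset=t_us / 1e6, letters=letters,
                    stimulus_class=stim_class,
                    trial_index=trial, sequence_index=seq, flash_index=flash,
                    is_target=target in letters))
                t_us += soa_us
    return StimulusSchedule(condition=condition, matrix=matrix,
                            targets=targets, events=tuple(events),
                            timing=timing)


def target_to_target_intervals(schedule: StimulusSchedule) -> list[int | None]:
    """Non-target flashes separating consecutive target flashes.

    Returns one entry per flash event: for target flashes the count of
    non-target flashes since the previous target flash of the same trial
    (``None`` for the first target flash of a trial, which has no
    predecessor), and ``None`` for non-target flashes.  An interval of 0
    is a "double flash" — the target set flashed twice in a row.
    """
    out: list[int | None] = [None] * len(schedule.events)
    last_target: dict[int, int] = {}
    gap: dict[int, int] = {}
    for i, e in enumerate(schedule.events):
        trial = e.trial_index
        if e.is_target:
            if trial in last_target:
                out[i] = gap[trial]
            gap[trial] = 0
            last_target[trial] = i
        else:
            if trial in gap:
                gap[trial] += 1
    return out


def write_event_log(schedule: StimulusSchedule, path: str | Path) -> None:
    """Write the flash-event log as TSV (one row per flash)."""
    schedule.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")


def read_event_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"letters": str})
    df["is_target"] = df["is_target"].astype(int)
    return df


def schedule_from_event_log(df: pd.DataFrame, condition: str | None = None,
                            timing: TimingConfig | None = None,
                            matrix: LetterMatrix | None = None,
                            ) -> StimulusSchedule:
    """Rebuild a schedule from a TSV event table.

    The spelled targets are not stored in the log; they are inferred per
    trial as the symbol common to all of that trial's target flash sets
    (ties resolved toward the smallest row-major matrix position).
    """
    matrix = matrix or make_letter_matrix()
    if condition is None:
        classes = set(df["stim_class"])
        condition = "RASP_F" if classes - {STIM_HIGHLIGHT} else "RC"
    if timing is None:
        n_seq = int(df["sequence"].max()) + 1
        timing = TimingConfig(sequences_per_trial=n_seq)

    targets = []
    for trial in sorted(df["trial"].unique()):
        sets = [frozenset(row) for row in
                df.loc[(df["trial"] == trial) & (df["is_target"] == 1),
                       "letters"]]
        common = frozenset.intersection(*sets) if sets else frozenset()
        if not common:
            raise ValueError(f"trial {trial}: no common target symbol")
        targets.append(min(common, key=matrix.position))

    events = tuple(
        FlashEvent(onset=float(r.onset_s), letters=frozenset(r.letters),
                   stimulus_class=r.stim_class, trial_index=int(r.trial),
                   sequence_index=int(r.sequence),
                   flash_index=int(r.flash), is_target=bool(r.is_target))
        for r in df.itertuples())
    return StimulusSchedule(condition=condition, matrix=matrix,
                            targets=tuple(targets), events=events,
                            timing=timing)
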