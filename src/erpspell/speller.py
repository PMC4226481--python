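"""Letter decoding, accuracy curves, ITR and chronological CV.

A trial's letter is decoded by evidence accumulation: every flash
contributes its classifier score to all six symbols it contained, and
the symbol with the largest accumulated evidence over the first n
sequences wins.  The same rule serves all three spellers — for RC it
reduces to picking the best row and best column and intersecting them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import train_rlda
from .paradigm import FLASHES_PER_SEQUENCE, StimulusSchedule


@dataclass
class SpellerResult:
    """Decoding outcome of one run at every sequence count."""

    condition: str
    targets: tuple[str, ...]
    decoded: dict[int, tuple[str, ...]]      # n_sequences -> symbols/trial
    accuracy: dict[int, float]               # n_sequences -> P(n)
    itr_bits_per_min: dict[int, float]
    selection_duration_s: dict[int, float]
    n_choices: int = 36


@dataclass
class CrossValidationResult:
    """Per-flash binary accuracy over chronologically contiguous folds."""

    fold_accuracies: tuple[float, ...]
    stratum: str = "all"
    mean_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        if any(not (0.0 <= a <= 1.0) for a in self.fold_accuracies):
            raise ValueError("fold accuracies must lie in [0, 1]")
        self.mean_accuracy = float(np.mean(self.fold_accuracies))


def decode_characters(scores: np.ndarray, schedule: StimulusSchedule,
                      n_sequences: int) -> tuple[str, ...]:
    """Decode one symbol per trial from per-flash classifier scores.

    Evidence for symbol l is the sum of scores of all flashes within
    the first ``n_sequences`` sequences whose letter set contains l.
    Ties break toward the smallest (row, col) matrix position.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != len(schedule.events):
        raise ValueError(f"{scores.size} scores for "
                         f"{len(schedule.events)} flash events")
    if not (1 <= n_sequences <= schedule.timing.sequences_per_trial):
        raise ValueError("n_sequences out of range")

    # symbols in row-major matrix order, so argmax tie-breaks correctly
    symbols = sorted(schedule.matrix.symbols,
                     key=lambda s: schedule.matrix.position(s))
    index = {s: i for i, s in enumerate(symbols)}

    decoded = []
    for trial in range(schedule.n_trials):
        evidence = np.zeros(len(symbols))
        for event, score in zip(schedule.events, scores):
            if (event.trial_index == trial
                    and event.sequence_index < n_sequences):
                for s in event.letters:
                    evidence[index[s]] += score
        decoded.append(symbols[int(np.argmax(evidence))])
    return tuple(decoded)


def accuracy_vs_sequences(decoded: dict[int, tuple[str, ...]],
                          truth: tuple[str, ...]) -> dict[int, float]:
    """Fraction of correctly decoded trials per sequence count."""
    out = {}
    for n, symbols in decoded.items():
        if len(symbols) != len(truth):
            raise ValueError("decoded/truth length mismatch")
        out[n] = float(np.mean([d == t for d, t in zip(symbols, truth)]))
    return out


def information_transfer_rate(P: float, N: int,
                              selection_duration: float) -> float:
    """Wolpaw ITR in bits/min for accuracy ``P`` over ``N`` choices.

    Bits per selection: B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)),
    with 0*log2(0) = 0 and B clamped to 0 below chance (P < 1/N); the
    rate is B * 60 / selection_duration.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (0.0 <= P <= 1.0):
        raise ValueError("P must lie in [0, 1]")
    if selection_duration <= 0:
        raise ValueError("selection duration must be positive")
    B = bits_per_selection(P, N)
    return B * 60.0 / selection_duration


def bits_per_selection(P: float, N: int) -> float:
    """The symmetric-channel bits/selection term of the Wolpaw ITR."""
    B = np.log2(N)
    if P > 0:
        B += P * np.log2(P)
    if P < 1:
        B += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(max(B, 0.0))


def selection_duration(timing, n_sequences: int) -> float:
    """Time to select one symbol: countdown + n full sequences, s."""
    return timing.countdown + n_sequences * FLASHES_PER_SEQUENCE * timing.soa


def evaluate_speller(scores: np.ndarray, schedule: StimulusSchedule,
                     n_choices: int = 36) -> SpellerResult:
    """Accuracy and ITR curves over 1..max sequence counts."""
    timing = schedule.timing
    decoded, acc, itr, dur = {}, {}, {}, {}
    for n in range(1, timing.sequences_per_trial + 1):
        decoded[n] = decode_characters(scores, schedule, n)
        dur[n] = selection_duration(timing, n)
    acc = accuracy_vs_sequences(decoded, schedule.targets)
    itr = {n: information_transfer_rate(acc[n], n_choices, dur[n])
           for n in acc}
    return SpellerResult(condition=schedule.condition,
                         targets=schedule.targets, decoded=decoded,
                         accuracy=acc, itr_bits_per_min=itr,
                         selection_duration_s=dur, n_choices=n_choices)


def chronological_cross_validation(X: np.ndarray, y: np.ndarray, k: int = 8,
                                   stratum: str = "all",
                                   stimulus_class: np.ndarray | None = None,
                                   ) -> CrossValidationResult:
    """k-fold CV with temporally contiguous folds, order preserved.

    Epochs (already in recording order) are split into k contiguous
    folds of near-equal size (earlier folds absorb remainders); each
    fold is tested once with the others pooled for training.  With
    ``stratum`` set to a stimulus class, epochs are restricted to that
    class *before* splitting.  Accuracy is per-flash binary accuracy at
    the natural threshold score > 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if stratum != "all":
        if stimulus_class is None:
            raise ValueError("stratum selection needs stimulus_class")
        mask = np.asarray(stimulus_class) == stratum
        X, y = X[mask], y[mask]
    n = X.shape[0]
    if n < k:
        raise ValueError(f"{n} epochs cannot form {k} folds")
    folds = np.array_split(np.arange(n), k)

    accs = []
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        y_train = y[train_mask]
        if y_train.all() or not y_train.any():
            raise ValueError("a training split contains a single class")
        model = train_rlda(X[train_mask], y_train)
        pred = model.score(X[test_idx]) > 0
        accs.append(float(np.mean(pred == y[test_idx])))
    return CrossValidationResult(fold_accuracies=tuple(accs),
                                 stratum=stratum)
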