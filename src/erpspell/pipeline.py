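"""End-to-end orchestration: simulate -> preprocess -> features ->
train -> decode -> statistics, at subject and study level.

The study design mirrors the offline copy-spelling protocol: per
speller condition a training run (one 24-symbol sentence) recorded on
one day and a test run (one 15-symbol sentence) on another.  The
classifier pipeline is fitted on the training run only — signed-r^2
intervals and LDA weights — and applied unchanged to the test run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import paradigm
from .classifier import RLDAModel, train_rlda
from .features import (DiscriminativeIntervals, interval_mean_features,
                       select_discriminative_intervals, signed_r_squared_map)
from .preprocessing import EpochSet, preprocess_run
from .simulate import SimulationConfig, StudyDataset, generate_study
from .speller import (CrossValidationResult, SpellerResult,
                      chronological_cross_validation, evaluate_speller)
from .stats import ComponentWindow, component_window_mean


@dataclass
class ConditionResult:
    """One condition of one subject, train->test."""

    condition: str
    model: RLDAModel
    intervals: DiscriminativeIntervals
    speller: SpellerResult
    cv: dict[str, CrossValidationResult]     # stratum -> result
    test_scores: np.ndarray                  # per test flash
    test_epochs: EpochSet
    component_means: dict[str, dict[str, float]] = field(
        default_factory=dict)                # component -> stratum -> uV


@dataclass
class SubjectResult:
    subject: int
    conditions: dict[str, ConditionResult]

    def accuracy_matrix(self) -> np.ndarray:
        """(3 spellers, 10 sequence counts) accuracy array (RC, RASP,
        RASP_F row order)."""
        rows = []
        for cond in paradigm.CONDITIONS:
            res = self.conditions[cond].speller
            rows.append([res.accuracy[n] for n in sorted(res.accuracy)])
        return np.array(rows)

    def itr_matrix(self) -> np.ndarray:
        rows = []
        for cond in paradigm.CONDITIONS:
            res = self.conditions[cond].speller
            rows.append([res.itr_bits_per_min[n]
                         for n in sorted(res.itr_bits_per_min)])
        return np.array(rows)


def _component_strata(epochs: EpochSet, condition: str,
                      ) -> dict[str, np.ndarray]:
    """Target-epoch masks for the ERP component contrasts."""
    meta = epochs.metadata
    targets = meta["is_target"].to_numpy().astype(bool)
    strata = {"target": targets}
    if condition == "RASP_F":
        for cls in (paradigm.STIM_SELF_FACE, paradigm.STIM_NON_SELF_FACE):
            strata[cls] = targets & (meta["stim_class"] == cls).to_numpy()
    return strata


def run_condition(dataset: StudyDataset, condition: str,
                  ) -> ConditionResult:
    """Fit on the training run and evaluate on the test run."""
    rec_train, sched_train = dataset[condition]["train"]
    rec_test, sched_test = dataset[condition]["test"]

    ep_train = preprocess_run(rec_train, sched_train)
    ep_test = preprocess_run(rec_test, sched_test)

    dmap = signed_r_squared_map(ep_train)
    intervals = select_discriminative_intervals(dmap)
    X_train = interval_mean_features(ep_train, intervals)
    model = train_rlda(X_train, ep_train.labels, intervals=intervals,
                       channels=ep_train.channels)

    X_test = interval_mean_features(ep_test, intervals)
    scores = model.score(X_test)
    speller_result = evaluate_speller(scores, sched_test)

    cv: dict[str, CrossValidationResult] = {
        "all": chronological_cross_validation(X_test, ep_test.labels)}
    if condition == "RASP_F":
        cls = ep_test.metadata["stim_class"].to_numpy()
        for stratum in (paradigm.STIM_SELF_FACE,
                        paradigm.STIM_NON_SELF_FACE):
            cv[stratum] = chronological_cross_validation(
                X_test, ep_test.labels, stratum=stratum,
                stimulus_class=cls)

    comp_means: dict[str, dict[str, float]] = {}
    for name in ("N170", "P300", "N400f"):
        win = ComponentWindow.standard(name)
        vals = component_window_mean(ep_test, win)
        comp_means[name] = {
            stratum: float(vals[mask].mean()) if mask.any() else np.nan
            for stratum, mask in
            _component_strata(ep_test, condition).items()}

    return ConditionResult(condition=condition, model=model,
                           intervals=intervals, speller=speller_result,
                           cv=cv, test_scores=scores, test_epochs=ep_test,
                           component_means=comp_means)


def run_subject(config: SimulationConfig | None = None,
                rng: np.random.Generator | int | None = None,
                subject: int = 0) -> SubjectResult:
    """Simulate and analyse one subject across all three conditions."""
    rng = np.random.default_rng(rng)
    dataset = generate_study(config, rng=rng)
    conditions = {cond: run_condition(dataset, cond)
                  for cond in paradigm.CONDITIONS}
    return SubjectResult(subject=subject, conditions=conditions)


def run_study(n_subjects: int, config: SimulationConfig | None = None,
              seed: int | None = None,
              subject_gain_range: tuple[float, float] = (0.8, 1.2),
              ) -> list[SubjectResult]:
    """Simulate a cohort; subjects differ in noise realization, flash
    randomization and a per-subject ERP gain factor drawn uniformly
    from ``subject_gain_range`` (emulating inter-subject SNR spread)."""
    config = config or SimulationConfig()
    root = np.random.SeedSequence(seed)
    results = []
    for i, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        gain = float(rng.uniform(*subject_gain_range))
        results.append(run_subject(config.scale_amplitudes(gain),
                                   rng=rng, subject=i))
    return results


def target_flash_outcomes(result: ConditionResult,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """(correct, tti) per target flash of the test run.

    A target flash counts as correct when the classifier score exceeds
    the decision threshold 0; used for the TTI accuracy profile.
    """
    meta = result.test_epochs.metadata
    is_target = meta["is_target"].to_numpy().astype(bool)
    tti = meta["tti"].to_numpy()[is_target]
    correct = (result.test_scores[is_target] > 0)
    return correct, tti
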