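"""Forward model: synthetic multichannel EEG for the three spellers.

The generator emulates what the analysis pipeline assumes about the real
recordings: 29-channel EEG sampled at 500 Hz containing stimulus-locked
ERP deflections superimposed on 1/f ("pink") background activity.

Per flash event the model adds, for every enabled component whose
amplitude table covers the event's (stimulus class, target) cell,

    amplitude [uV] x TTI scale (P300 only) x half-sine kernel(t)
                  x Gaussian spatial profile(channel)

to the ongoing signal.  Targets receive a P300 (positive, peak Cz);
face-class flashes receive an N170 (negative, peak PO7, slightly larger
for targets); target face flashes additionally receive an N400f
(negative, peak Cz) that is larger for the self face than for non-self
faces — the face-familiarity effect the RASP-F speller exploits.

The P300 is attenuated when the preceding target flash is recent (short
target-to-target interval, TTI): double-flashed targets (TTI 0) keep
only a fraction of the amplitude, recovering to full size at TTI >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import fft as scipy_fft

from . import paradigm
from .montage import CHANNELS, spatial_weights
from .paradigm import (StimulusSchedule, TimingConfig, build_schedule,
                       target_to_target_intervals)

TRAIN_SENTENCE = "BRAIN_COMPUTER_INTERFACE"
TEST_SENTENCE = "KOREAUNIVERSITY"


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component of the forward model.

    ``amplitudes`` maps ``(stimulus_class, is_target)`` cells to peak
    amplitude in uV (always >= 0; the sign is carried by ``polarity``).
    Cells absent from the table contribute nothing.
    """

    name: str
    window_ms: tuple[float, float]
    polarity: int                 # +1 or -1
    peak_channel: str
    spread: float                 # Gaussian spatial decay, radians
    amplitudes: Mapping[tuple[str, bool], float]
    tti_sensitive: bool = False   # P300 refractoriness

    def __post_init__(self) -> None:
        lo, hi = self.window_ms
        if not (0 <= lo < hi <= 800):
            raise ValueError("component window must lie within 0-800 ms")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes are magnitudes; sign via polarity")


def default_components() -> tuple[ComponentSpec, ...]:
    """Component table reproducing the qualitative speller ordering.

    Amplitudes are free parameters of the simulation (they are not
    estimates of any recorded data); the defaults make RASP-F the most
    discriminable condition via the extra face components.
    """
    target_p300 = {(cls, True): 5.0 for cls in
                   (paradigm.STIM_HIGHLIGHT, paradigm.STIM_SELF_FACE,
                    paradigm.STIM_NON_SELF_FACE)}
    return (
        ComponentSpec("P300", (280.0, 370.0), +1, "Cz", 0.8,
                      target_p300, tti_sensitive=True),
        ComponentSpec("N170", (130.0, 200.0), -1, "PO7", 0.6, {
            (paradigm.STIM_SELF_FACE, False): 3.0,
            (paradigm.STIM_NON_SELF_FACE, False): 3.0,
            (paradigm.STIM_SELF_FACE, True): 4.0,
            (paradigm.STIM_NON_SELF_FACE, True): 4.0,
        }),
        ComponentSpec("N400f", (400.0, 550.0), -1, "Cz", 0.8, {
            (paradigm.STIM_SELF_FACE, True): 4.0,
            (paradigm.STIM_NON_SELF_FACE, True): 2.0,
        }),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters (units in field comments)."""

    channels: tuple[str, ...] = CHANNELS
    sample_rate: float = 500.0          # Hz, acquisition rate
    noise_sigma: float = 6.0            # uV, total background std
    noise_exponent: float = 1.0         # 1/f^alpha spectral slope
    common_mode_fraction: float = 0.3   # share of sigma common to channels
    components: tuple[ComponentSpec, ...] = field(
        default_factory=default_components)
    tti_attenuation: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.4, 1: 0.6, 2: 0.8, 3: 1.0})
    timing: TimingConfig = field(default_factory=TimingConfig)
    session_scale: float = 0.95         # test-run amplitude factor
    train_sentence: str = TRAIN_SENTENCE
    test_sentence: str = TEST_SENTENCE

    def __post_init__(self) -> None:
        vals = list(self.tti_attenuation.values())
        if any(not (0 < v <= 1) for v in vals):
            raise ValueError("tti_attenuation values must be in (0, 1]")
        keys = sorted(self.tti_attenuation)
        ordered = [self.tti_attenuation[k] for k in keys]
        if any(a > b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("tti_attenuation must be nondecreasing in TTI")
        if self.tti_attenuation[max(keys)] != 1.0:
            raise ValueError("tti_attenuation must reach 1 at its top bin")

    def tti_scale(self, tti: int | None) -> float:
        """P300 amplitude factor for a given TTI (None = no predecessor)."""
        if tti is None:
            return 1.0
        top = max(self.tti_attenuation)
        return float(self.tti_attenuation[min(int(tti), top)])

    def scale_amplitudes(self, factor: float) -> "SimulationConfig":
        comps = tuple(
            replace(c, amplitudes={k: v * factor
                                   for k, v in c.amplitudes.items()})
            for c in self.components)
        return replace(self, components=comps)


@dataclass
class Recording:
    """Multichannel signal plus sample-indexed flash markers."""

    signal: np.ndarray            # (n_channels, n_samples), uV
    rate: float                   # Hz
    channels: tuple[str, ...]
    marker_samples: np.ndarray    # (n_events,), sample index of each flash

    def __post_init__(self) -> None:
        if self.signal.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")
        if self.marker_samples.size and (
                self.marker_samples.max() >= self.signal.shape[1]
                or self.marker_samples.min() < 0):
            raise ValueError("marker outside recorded signal")

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.rate


@dataclass
class StudyDataset:
    """One simulated subject: train + test run per speller condition."""

    runs: dict[str, dict[str, tuple[Recording, StimulusSchedule]]]
    config: SimulationConfig

    def __getitem__(self, key: str):
        return self.runs[key]


def erp_kernel(window_ms: tuple[float, float], times_ms: np.ndarray,
               ) -> np.ndarray:
    """Unit-peak half-sine bump supported exactly on ``window_ms``.

    Zero outside the window, sin(pi * (t-lo)/(hi-lo)) inside; the peak
    value 1 is attained at the window midpoint.
    """
    lo, hi = window_ms
    t = np.asarray(times_ms, dtype=float)
    out = np.zeros_like(t)
    inside = (t >= lo) & (t <= hi)
    out[inside] = np.sin(np.pi * (t[inside] - lo) / (hi - lo))
    return out


def pink_noise(n_channels: int, n_samples: int, rate: float, sigma: float,
               exponent: float, common_fraction: float,
               rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise, per-channel independent plus a common-mode term.

    The common-mode share emulates the broad spatial correlation of real
    EEG background activity; the two parts are scaled so the total
    per-channel standard deviation equals ``sigma``.
    """
    if sigma == 0:
        return np.zeros((n_channels, n_samples))

    nfft = scipy_fft.next_fast_len(n_samples, real=True)

    def _one(n_series: int) -> np.ndarray:
        white = rng.standard_normal((n_series, nfft))
        spec = scipy_fft.rfft(white, axis=1)
        freqs = scipy_fft.rfftfreq(nfft, d=1.0 / rate)
        shaping = np.zeros_like(freqs)
        shaping[1:] = freqs[1:] ** (-exponent / 2.0)
        series = scipy_fft.irfft(spec * shaping, n=nfft,
                                 axis=1)[:, :n_samples]
        series /= series.std(axis=1, keepdims=True)
        return series

    indep = _one(n_channels)
    if common_fraction > 0:
        common = _one(1)
        w_common = sigma * common_fraction
        w_indep = sigma * np.sqrt(1.0 - common_fraction**2)
        return w_indep * indep + w_common * common
    return sigma * indep


def simulate_recording(schedule: StimulusSchedule, config: SimulationConfig,
                       rng: np.random.Generator | int | None = None,
                       duration: float | None = None) -> Recording:
    """Render a schedule into a continuous noisy EEG recording."""
    rng = np.random.default_rng(rng)
    rate = config.sample_rate
    tail = 1.0  # s of signal after the last flash (epoch window + slack)
    needed = (schedule.events[-1].onset + tail) if schedule.events else tail
    if duration is None:
        duration = needed
    elif duration < needed:
        raise ValueError(
            f"schedule needs {needed:.2f} s but duration is {duration:.2f} s")
    n_samples = int(round(duration * rate))
    n_ch = len(config.channels)

    signal = pink_noise(n_ch, n_samples, rate, config.noise_sigma,
                        config.noise_exponent, config.common_mode_fraction,
                        rng)

    ttis = target_to_target_intervals(schedule)
    # round half up: onsets land exactly on .5 samples (SOA x rate =
    # 92.5), and this rule survives the 6-decimal event-log round trip
    markers = np.array([int(np.floor(e.onset * rate + 0.5))
                        for e in schedule.events])

    for comp in config.components:
        lo, hi = comp.window_ms
        i0 = int(np.floor(lo * rate / 1000.0))
        i1 = int(np.ceil(hi * rate / 1000.0))
        times = np.arange(i0, i1 + 1) * 1000.0 / rate
        kernel = comp.polarity * erp_kernel(comp.window_ms, times)
        topo = spatial_weights(comp.peak_channel, comp.spread,
                               config.channels)
        patch = np.outer(topo, kernel)          # (n_ch, n_kernel)
        for event, marker, tti in zip(schedule.events, markers, ttis):
            amp = comp.amplitudes.get(
                (event.stimulus_class, event.is_target), 0.0)
            if amp == 0.0:
                continue
            if comp.tti_sensitive and event.is_target:
                amp *= config.tti_scale(tti)
            sl = slice(marker + i0, marker + i0 + kernel.size)
            if sl.stop > n_samples:
                raise ValueError("flash event too close to recording end")
            signal[:, sl] += amp * patch

    return Recording(signal=signal, rate=rate, channels=config.channels,
                     marker_samples=markers)


def generate_study(config: SimulationConfig | None = None,
                   rng: np.random.Generator | int | None = None,
                   ) -> StudyDataset:
    """Simulate one subject's full study: 3 conditions x train/test.

    Runs draw independent noise and schedules from ``rng``; test runs
    have all component amplitudes scaled by ``config.session_scale`` to
    emulate session-to-session transfer loss (training and test were
    recorded on different days).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(rng)
    runs: dict[str, dict[str, tuple[Recording, StimulusSchedule]]] = {}
    for condition in paradigm.CONDITIONS:
        runs[condition] = {}
        for phase, sentence in (("train", config.train_sentence),
                                ("test", config.test_sentence)):
            schedule = build_schedule(condition, sentence,
                                      timing=config.timing, rng=rng)
            cfg = config
            if phase == "test" and config.session_scale != 1.0:
                cfg = config.scale_amplitudes(config.session_scale)
            rec = simulate_recording(schedule, cfg, rng=rng)
            runs[condition][phase] = (rec, schedule)
    return StudyDataset(runs=runs, config=config)
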