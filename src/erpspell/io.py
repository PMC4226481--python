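"""File interfaces: EDF recordings, event logs, epoch archives, configs.

Recordings travel as plain EDF (16-bit European Data Format) with a
companion TSV event log and a JSON sidecar holding the simulation
parameters.  The EDF writer here emits minimal single-segment EDF;
reading goes through MNE's EDF reader, so round-trips are checked
against an independent implementation of the format.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .paradigm import (StimulusSchedule, TimingConfig, build_schedule,
                       read_event_log, write_event_log)
from .simulate import Recording, SimulationConfig

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF (uV physical units).

    Uses 1-second data records; the final record is zero-padded if the
    signal length is not a whole number of seconds.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    spr = int(round(rate))                      # samples per record
    n_ch, n_samples = rec.signal.shape
    n_records = int(np.ceil(n_samples / spr))

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samples] = rec.signal
    # per-channel symmetric physical range, rounded up for clean headers
    span = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    phys_max = np.ceil(span * 10.0) / 10.0
    scale = _EDF_DIG_MAX / phys_max
    digital = np.clip(np.round(padded * scale[:, None]),
                      _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),                  # local patient id
        _field("Startdate X X X X", 80),        # local recording id
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(256 * (1 + n_ch), 8),
        _field("", 44),
        _field(n_records, 8), _field(1, 8),     # record duration 1 s
        _field(n_ch, 4),
    ])
    per_signal = b"".join([
        b"".join(_field(c, 16) for c in rec.channels),
        b"".join(_field("AgAgCl electrode", 80) for _ in rec.channels),
        b"".join(_field("uV", 8) for _ in rec.channels),
        b"".join(_field(f"{-m:.1f}", 8) for m in phys_max),
        b"".join(_field(f"{m:.1f}", 8) for m in phys_max),
        b"".join(_field(_EDF_DIG_MIN, 8) for _ in rec.channels),
        b"".join(_field(_EDF_DIG_MAX, 8) for _ in rec.channels),
        b"".join(_field("", 80) for _ in rec.channels),
        b"".join(_field(spr, 8) for _ in rec.channels),
        b"".join(_field("", 32) for _ in rec.channels),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # record-major interleaving: per record, each signal's samples
        blocks = digital.reshape(n_ch, n_records, spr)
        fh.write(np.ascontiguousarray(
            blocks.transpose(1, 0, 2)).tobytes())


def read_edf(path: str | Path,
             marker_samples: np.ndarray | None = None) -> Recording:
    """Read an EDF recording (via MNE) back into uV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6               # MNE returns Volts
    markers = (np.asarray(marker_samples, dtype=int)
               if marker_samples is not None
               else np.empty(0, dtype=int))
    return Recording(signal=signal, rate=float(raw.info["sfreq"]),
                     channels=tuple(raw.ch_names), marker_samples=markers)


def write_run(rec: Recording, schedule: StimulusSchedule,
              config: SimulationConfig, out_dir: str | Path,
              stem: str) -> dict[str, Path]:
    """Write one run: EDF + event TSV + JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": out_dir / f"{stem}.edf",
        "events": out_dir / f"{stem}_events.tsv",
        "sidecar": out_dir / f"{stem}.json",
    }
    write_edf(rec, paths["edf"])
    write_event_log(schedule, paths["events"])
    paths["sidecar"].write_text(json.dumps(
        simulation_config_dict(config), indent=2))
    return paths


def read_run(edf_path: str | Path, events_path: str | Path,
             ) -> tuple[Recording, "np.ndarray", "object"]:
    """Read a run back: recording plus its event table.

    The event log carries onsets in seconds; marker sample indices are
    reconstructed at the EDF's sampling rate.
    """
    events = read_event_log(events_path)
    rec = read_edf(edf_path)
    markers = np.floor(events["onset_s"].to_numpy() * rec.rate
                       + 0.5).astype(int)    # round half up, as simulated
    rec.marker_samples = markers
    return rec, events


def save_epochs(epochs, path: str | Path) -> None:
    """Persist an EpochSet as a compressed npz with a JSON header."""
    header = {
        "channels": list(epochs.channels),
        "metadata": epochs.metadata.to_json(orient="split"),
    }
    np.savez_compressed(path, data=epochs.data, times_ms=epochs.times_ms,
                        labels=epochs.labels,
                        header=np.frombuffer(
                            json.dumps(header).encode(), dtype=np.uint8))


def load_epochs(path: str | Path):
    import pandas as pd

    from .preprocessing import EpochSet
    with np.load(path) as z:
        header = json.loads(bytes(z["header"].tobytes()).decode())
        meta = pd.read_json(__import__("io").StringIO(header["metadata"]),
                            orient="split")
        return EpochSet(data=z["data"], times_ms=z["times_ms"],
                        labels=z["labels"],
                        channels=tuple(header["channels"]),
                        metadata=meta)


def simulation_config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["components"] = [
        {**asdict(c), "amplitudes": [
            {"stimulus_class": k[0], "is_target": k[1], "uV": v}
            for k, v in c.amplitudes.items()]}
        for c in config.components]
    d["tti_attenuation"] = {str(k): v
                            for k, v in config.tti_attenuation.items()}
    return d


def load_study_config(path: str | Path) -> dict:
    """Read a YAML study/schedule configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def schedule_from_config(cfg: dict) -> StimulusSchedule:
    """Build a schedule from a config mapping.

    Recognized keys: condition, sentence, seed and optional timing
    overrides (flash_duration, isi, countdown, sequences_per_trial).
    """
    timing_keys = ("flash_duration", "isi", "countdown",
                   "sequences_per_trial")
    timing = TimingConfig(**{k: cfg[k] for k in timing_keys if k in cfg})
    return build_schedule(cfg["condition"].upper(), cfg["sentence"],
                          timing=timing, rng=cfg.get("seed"))
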