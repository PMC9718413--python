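"""CSV/JSON readers and writers, run configuration, checksum manifest.

File conventions (see docs/formats.md): UTF-8 comma-separated CSV with a
header row and "." decimals; times in ms, amplitudes in uV.  Continuous
recordings are a data CSV (time_ms, eeg_uV, eog_uV) plus an events CSV
(time_ms, label).  Every simulated dataset directory carries a
manifest.json with the resolved configuration, seed and SHA-256 checksums
so a run can be verified and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import game, synth
from . import signal_core as sc
from .errors import FormatError

SIGNAL_COLUMNS = ("time_ms", "eeg_uV", "eog_uV")
EVENT_COLUMNS = ("time_ms", "label")


def signal_to_frames(sig: sc.SampledSignal) -> tuple[pd.DataFrame, pd.DataFrame]:
    t = np.arange(sig.n_samples) * 1000.0 / sig.sample_rate
    data = pd.DataFrame({"time_ms": t, "eeg_uV": sig.eeg, "eog_uV": sig.eog})
    events = pd.DataFrame(sig.events, columns=list(EVENT_COLUMNS))
    return data, events


def write_signal_csv(sig: sc.SampledSignal, data_path, events_path) -> None:
    data, events = signal_to_frames(sig)
    data.to_csv(data_path, index=False)
    events.to_csv(events_path, index=False)


def read_signal_csv(data_path, events_path) -> sc.SampledSignal:
    """Load a continuous recording; raises :class:`FormatError` with the
    offending file when the schema does not match."""
    data = pd.read_csv(data_path)
    if tuple(data.columns[:3]) != SIGNAL_COLUMNS:
        raise FormatError(f"{data_path}: expected columns {SIGNAL_COLUMNS}, "
                          f"got {tuple(data.columns)}")
    if len(data) < 2:
        raise FormatError(f"{data_path}: need at least two samples")
    dt = np.diff(data["time_ms"].to_numpy())
    if not np.allclose(dt, dt[0], atol=1e-6):
        raise FormatError(f"{data_path}: sample times must be uniform")
    events = pd.read_csv(events_path)
    if tuple(events.columns[:2]) != EVENT_COLUMNS:
        raise FormatError(f"{events_path}: expected columns {EVENT_COLUMNS}")
    rate = 1000.0 / float(dt[0])
    try:
        return sc.SampledSignal(
            rate, data["eeg_uV"].to_numpy(), data["eog_uV"].to_numpy(),
            tuple(zip(events["time_ms"].astype(float), events["label"].astype(str))),
        )
    except Exception as e:  # label/time validation
        raise FormatError(f"{events_path}: {e}") from e


def read_edf(path):  # pragma: no cover - optional dependency
    """Optional EDF reader (requires mne); channels are taken in file
    order as (EEG, EOG) and annotations as events."""
    try:
        import mne
    except ImportError as e:
        raise FormatError("EDF support requires the optional 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    events = tuple(
        (float(on) * 1000.0, str(desc))
        for on, desc in zip(raw.annotations.onset, raw.annotations.description)
        if desc in sc.EVENT_LABELS
    )
    return sc.SampledSignal(float(raw.info["sfreq"]), data[0], data[1], events)


def write_epoch_csv(epoch: sc.Epoch, path) -> None:
    """Epoch dump: header names the span and type."""
    t = epoch.times_ms
    frame = pd.DataFrame({
        f"time_ms[{t[0]:g}..{t[-1]:g}]({epoch.trial_type})": t,
        "eeg_uV": epoch.samples,
        "eog_uV": epoch.eog_samples,
    })
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Seed plus every module parameter block; JSON round-trips losslessly
    and every run writes its resolved config next to its outputs."""

    seed: int = 0
    n_per_group: int = 8
    n_bad_trials: int = 96
    calibration_trials: int = 200
    noise_sd: float = 8.0
    blink_rate_per_min: float = 4.0
    keep_trial_logs: bool = False
    filter_band_hz: tuple = sc.FILTER_BAND_HZ
    filter_order: int = sc.FILTER_ORDER
    artifact_threshold_uv: float = sc.ARTIFACT_THRESHOLD_UV
    stage_fractions: tuple = game.STAGE_FRACTIONS
    attempts_per_stage: int = 10
    sounds_per_session: int = 300
    soa_ms: float = 800.0
    sessions_per_game_per_day: int = 4

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter_band_hz"] = list(self.filter_band_hz)
        d["stage_fractions"] = list(self.stage_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise FormatError(f"unknown config keys: {sorted(extra)}")
        d = dict(d)
        if "filter_band_hz" in d:
            d["filter_band_hz"] = tuple(d["filter_band_hz"])
        if "stage_fractions" in d:
            d["stage_fractions"] = tuple(d["stage_fractions"])
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            return cls.from_dict(json.loads(Path(path).read_text()))
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: invalid JSON ({e})") from e

    def experiment_config(self) -> synth.ExperimentConfig:
        return synth.ExperimentConfig(
            n_per_group=self.n_per_group,
            n_bad_trials=self.n_bad_trials,
            calibration_trials=self.calibration_trials,
            game=game.GameConfig(
                stage_fractions=self.stage_fractions,
                attempts_per_stage=self.attempts_per_stage,
                sounds_per_session=self.sounds_per_session,
                soa_ms=self.soa_ms,
                sessions_per_game_per_day=self.sessions_per_game_per_day,
            ),
            noise_sd=self.noise_sd,
            blink_rate_per_min=self.blink_rate_per_min,
            keep_trial_logs=self.keep_trial_logs,
        )


DATASET_TABLES = ("profiles", "calibration", "bad_counts", "bad_trials",
                  "mmn_normalized", "sessions", "training_summary")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_dataset(dataset: synth.ExperimentDataset, out_dir, config: RunConfig) -> Path:
    """Write all tables, the resolved config and a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in DATASET_TABLES:
        getattr(dataset, name).to_csv(out / f"{name}.csv", index=False)
    if dataset.trial_logs is not None:
        dataset.trial_logs.to_csv(out / "trial_logs.csv", index=False)
    config.to_json(out / "config.json")
    manifest = dict(dataset.manifest)
    manifest["checksums"] = {
        p.name: sha256_file(p) for p in sorted(out.glob("*.csv"))
    }
    manifest["checksums"]["config.json"] = sha256_file(out / "config.json")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_dataset_tables(dataset_dir) -> dict:
    """Load the dataset CSVs; missing required tables raise FormatError."""
    out = {}
    d = Path(dataset_dir)
    for name in DATASET_TABLES:
        p = d / f"{name}.csv"
        if not p.exists():
            raise FormatError(f"dataset incomplete: missing {p.name}")
        out[name] = pd.read_csv(p)
    return out


def verify_dataset(dataset_dir) -> list:
    """Check the manifest checksums; return the list of mismatched files."""
    d = Path(dataset_dir)
    mpath = d / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"{dataset_dir}: no manifest.json")
    manifest = json.loads(mpath.read_text())
    bad = []
    for name, digest in manifest.get("checksums", {}).items():
        p = d / name
        if not p.exists() or sha256_file(p) != digest:
            bad.append(name)
    return bad
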