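"""Deterministic ERP signal chain.

Single-channel EEG (frontal electrode) plus an EOG channel, sampled
continuously with stimulus event markers.  The chain is

    band-pass filter -> epoch extraction -> baseline correction ->
    artifact rejection -> type-wise averaging -> MMN peak scoring

in exactly that order.  All filters are causal so the same code path serves
offline and real-time use.  Times are milliseconds, amplitudes microvolts,
sample indices 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from .errors import BoundaryError, EstimationError, ParameterError

DEFAULT_SAMPLE_RATE = 500.0
"""Acquisition rate of the recording device (Hz)."""

FILTER_BAND_HZ = (0.1, 35.0)
"""Default band-pass edges applied to EEG and EOG."""

FILTER_ORDER = 4
"""Butterworth order per band edge (8 poles total for the band-pass)."""

EPOCH_PRE_MS = 100.0
EPOCH_POST_MS = 500.0
"""Peri-stimulus window: half-open [-pre, +post) relative to onset."""

MMN_SEARCH_WINDOW_MS = (100.0, 250.0)
"""Latency window searched for the most negative difference-wave sample."""

ARTIFACT_THRESHOLD_UV = 40.0
"""Rejection threshold: any |sample| strictly above this flags the epoch."""

EVENT_LABELS = frozenset({"standard", "deviant", "tone_std", "tone_dev"})

_TRIAL_TYPE = {
    "standard": "standard",
    "deviant": "deviant",
    "tone_std": "standard",
    "tone_dev": "deviant",
}


def canonical_trial_type(label: str) -> str:
    """Map an event label to its trial type (``standard`` or ``deviant``).

    Tone labels are used by the maximal-MMN calibration oddball; they play
    the same roles as the word standards/deviants in the chain.
    """
    try:
        return _TRIAL_TYPE[label]
    except KeyError:
        raise ParameterError(f"unknown event label {label!r}") from None


@dataclass(frozen=True)
class SampledSignal:
    """Continuous EEG + EOG recording with stimulus event markers.

    Parameters
    ----------
    sample_rate
        Sampling rate in Hz (> 0).
    eeg, eog
        Amplitude series in microvolts, equal length.
    events
        Sequence of ``(time_ms, label)`` with labels from the closed
        vocabulary {standard, deviant, tone_std, tone_dev} and times inside
        the recording.
    """

    sample_rate: float
    eeg: np.ndarray
    eog: np.ndarray
    events: tuple = ()

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be positive")
        object.__setattr__(self, "eeg", np.asarray(self.eeg, dtype=float))
        object.__setattr__(self, "eog", np.asarray(self.eog, dtype=float))
        if self.eeg.shape != self.eog.shape or self.eeg.ndim != 1:
            raise ParameterError("eeg and eog must be 1-D arrays of equal length")
        events = tuple((float(t), str(lab)) for t, lab in self.events)
        dur = self.duration_ms
        for t, lab in events:
            if lab not in EVENT_LABELS:
                raise ParameterError(f"unknown event label {lab!r}")
            if not (0.0 <= t < dur):
                raise ParameterError(f"event at {t} ms outside recording of {dur} ms")
        object.__setattr__(self, "events", events)

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sample_rate


@dataclass(eq=False)
class Epoch:
    """One peri-stimulus window of EEG and EOG.

    Identity semantics (no value equality): epochs are mutable containers
    tracked individually by the online FIFO buffers.

    ``baseline_mean`` is ``None`` until :func:`baseline_correct` runs;
    ``is_artifact`` is ``None`` until the rejection gate runs.
    """

    samples: np.ndarray
    eog_samples: np.ndarray
    trial_type: str
    sample_rate: float = DEFAULT_SAMPLE_RATE
    pre_ms: float = EPOCH_PRE_MS
    baseline_mean: float | None = None
    eog_baseline_mean: float | None = None
    is_artifact: bool | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.eog_samples = np.asarray(self.eog_samples, dtype=float)
        if self.samples.shape != self.eog_samples.shape:
            raise ParameterError("EEG and EOG epoch spans differ")
        if self.trial_type not in ("standard", "deviant"):
            raise ParameterError(f"bad trial_type {self.trial_type!r}")

    @property
    def n_pre(self) -> int:
        """Number of pre-stimulus samples (the baseline segment)."""
        return int(round(self.pre_ms * self.sample_rate / 1000.0))

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times relative to stimulus onset."""
        step = 1000.0 / self.sample_rate
        return (np.arange(self.samples.shape[0]) - self.n_pre) * step

    def copy(self) -> "Epoch":
        return Epoch(
            self.samples.copy(), self.eog_samples.copy(), self.trial_type,
            self.sample_rate, self.pre_ms, self.baseline_mean,
            self.eog_baseline_mean, self.is_artifact,
        )


@dataclass(frozen=True)
class DifferenceWave:
    """Deviant-average minus standard-average over the epoch span."""

    samples: np.ndarray
    n_standard: int
    n_deviant: int
    sample_rate: float = DEFAULT_SAMPLE_RATE
    pre_ms: float = EPOCH_PRE_MS

    def __post_init__(self):
        if self.n_standard <= 0 or self.n_deviant <= 0:
            raise ParameterError("difference wave requires epochs of both types")


@dataclass
class MMNEstimate:
    """MMN amplitude (absolute value of the most negative peak, in uV)
    and its latency; ``normalized`` is the fraction of the maximal MMN."""

    amplitude: float
    peak_latency_ms: float
    normalized: float | None = None

    def __post_init__(self):
        if self.amplitude < 0:
            raise ParameterError("MMN amplitude is defined as an absolute value")


# ---------------------------------------------------------------------------
# operations


def design_bandpass(
    low: float = FILTER_BAND_HZ[0],
    high: float = FILTER_BAND_HZ[1],
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Second-order sections of the causal Butterworth band-pass.

    ``order`` is per band edge; the resulting band-pass has ``2 * order``
    poles.  Raises :class:`ParameterError` on invalid edges.
    """
    if not (0.0 < low < high < sample_rate / 2.0):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < Nyquist; got ({low}, {high})"
        )
    return sps.butter(order, [low, high], btype="band", fs=sample_rate, output="sos")


def bandpass_filter(
    sig: SampledSignal,
    low: float = FILTER_BAND_HZ[0],
    high: float = FILTER_BAND_HZ[1],
    order: int = FILTER_ORDER,
) -> SampledSignal:
    """Apply the causal band-pass to both channels; events pass through.

    The filter is run with zero initial state, so output at time t depends
    only on input samples at times <= t (streaming-compatible).
    """
    sos = design_bandpass(low, high, sig.sample_rate, order)
    return SampledSignal(
        sig.sample_rate,
        sps.sosfilt(sos, sig.eeg),
        sps.sosfilt(sos, sig.eog),
        sig.events,
    )


def event_sample_index(time_ms: float, sample_rate: float) -> int:
    """Index of the nearest sample at or after the event onset."""
    return int(math.ceil(time_ms * sample_rate / 1000.0 - 1e-9))


def extract_epoch(
    sig: SampledSignal,
    event_time_ms: float,
    trial_type: str,
    pre_ms: float = EPOCH_PRE_MS,
    post_ms: float = EPOCH_POST_MS,
) -> Epoch:
    """Cut the half-open [-pre, +post) window around an event onset.

    Raises :class:`BoundaryError` when the window leaves the recording;
    callers skip (and log) such trials.
    """
    i0 = event_sample_index(event_time_ms, sig.sample_rate)
    n_pre = int(round(pre_ms * sig.sample_rate / 1000.0))
    n_post = int(round(post_ms * sig.sample_rate / 1000.0))
    lo, hi = i0 - n_pre, i0 + n_post
    if lo < 0 or hi > sig.n_samples:
        raise BoundaryError(
            f"epoch window [{lo}, {hi}) outside recording of {sig.n_samples} samples"
        )
    return Epoch(
        sig.eeg[lo:hi].copy(), sig.eog[lo:hi].copy(),
        canonical_trial_type(trial_type), sig.sample_rate, pre_ms,
    )


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract the pre-stimulus mean from each channel (idempotent).

    The mean over the [-pre, 0) segment is removed independently from the
    EEG and EOG spans; the removed EEG mean is recorded.  Applying the
    correction twice equals applying it once, and the recorded baseline
    keeps referring to the original raw epoch.
    """
    out = epoch.copy()
    n = out.n_pre
    b_eeg = float(np.mean(out.samples[:n]))
    b_eog = float(np.mean(out.eog_samples[:n]))
    out.samples = out.samples - b_eeg
    out.eog_samples = out.eog_samples - b_eog
    out.baseline_mean = (epoch.baseline_mean or 0.0) + b_eeg
    out.eog_baseline_mean = (epoch.eog_baseline_mean or 0.0) + b_eog
    return out


def is_artifact(epoch: Epoch, threshold_uv: float = ARTIFACT_THRESHOLD_UV) -> bool:
    """True iff any EEG *or* EOG sample strictly exceeds the threshold.

    The comparison is strict (">"): a sample at exactly the threshold does
    not flag the epoch.  Applied after baseline correction in the chain.
    """
    return bool(
        np.max(np.abs(epoch.samples)) > threshold_uv
        or np.max(np.abs(epoch.eog_samples)) > threshold_uv
    )


def average_epochs(epochs: Sequence[Epoch], trial_type: str) -> np.ndarray:
    """Pointwise mean EEG waveform over accepted epochs of one type.

    Epochs flagged as artifacts are excluded; raises
    :class:`EstimationError` when nothing remains.
    """
    keep = [e.samples for e in epochs
            if e.trial_type == trial_type and e.is_artifact is not True]
    if not keep:
        raise EstimationError(f"no accepted {trial_type} epochs to average")
    return np.mean(np.stack(keep), axis=0)


def difference_wave(epochs: Sequence[Epoch]) -> DifferenceWave:
    """Deviant-minus-standard average over accepted epochs."""
    std = average_epochs(epochs, "standard")
    dev = average_epochs(epochs, "deviant")
    n_std = sum(1 for e in epochs
                if e.trial_type == "standard" and e.is_artifact is not True)
    n_dev = sum(1 for e in epochs
                if e.trial_type == "deviant" and e.is_artifact is not True)
    e0 = epochs[0]
    return DifferenceWave(dev - std, n_std, n_dev, e0.sample_rate, e0.pre_ms)


def compute_mmn(
    std_avg: np.ndarray,
    dev_avg: np.ndarray,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    pre_ms: float = EPOCH_PRE_MS,
    search_window_ms: tuple[float, float] = MMN_SEARCH_WINDOW_MS,
) -> MMNEstimate:
    """Score the MMN from type averages aligned on the same epoch span.

    amplitude = |most negative difference-wave sample| within the search
    window; latency = time of that sample, ties broken toward the earliest
    latency (argmin returns the first minimum).
    """
    std_avg = np.asarray(std_avg, dtype=float)
    dev_avg = np.asarray(dev_avg, dtype=float)
    if std_avg.shape != dev_avg.shape or std_avg.ndim != 1:
        raise ParameterError("averages must be 1-D arrays of equal length")
    diff = dev_avg - std_avg
    n_pre = int(round(pre_ms * sample_rate / 1000.0))
    lo_ms, hi_ms = search_window_ms
    i_lo = n_pre + int(math.ceil(lo_ms * sample_rate / 1000.0 - 1e-9))
    i_hi = n_pre + int(math.floor(hi_ms * sample_rate / 1000.0 + 1e-9))
    if not (0 <= i_lo <= i_hi < diff.shape[0]):
        raise ParameterError("search window outside the epoch span")
    win = diff[i_lo : i_hi + 1]
    k = int(np.argmin(win))
    latency_ms = (i_lo + k - n_pre) * 1000.0 / sample_rate
    return MMNEstimate(abs(float(win[k])), latency_ms)


@dataclass
class TrialRecord:
    """Per-trial outcome of the epoching chain (for logs and streaming)."""

    index: int
    time_ms: float
    label: str
    trial_type: str
    epoch: Epoch | None
    accepted: bool
    reason: str = ""


def iter_trials(
    sig: SampledSignal,
    threshold_uv: float = ARTIFACT_THRESHOLD_UV,
    band: tuple[float, float] | None = FILTER_BAND_HZ,
    order: int = FILTER_ORDER,
) -> Iterator[TrialRecord]:
    """Run filter -> epoch -> baseline -> reject over every event, in order.

    Yields one :class:`TrialRecord` per event.  Boundary-violating events
    and artifact epochs are yielded with ``accepted=False`` (the epoch is
    still attached for artifacts, ``None`` for boundary skips).
    Pass ``band=None`` for pre-filtered input.
    """
    if band is not None:
        sig = bandpass_filter(sig, band[0], band[1], order)
    for i, (t, lab) in enumerate(sig.events):
        ttype = canonical_trial_type(lab)
        try:
            ep = extract_epoch(sig, t, lab)
        except BoundaryError:
            yield TrialRecord(i, t, lab, ttype, None, False, "boundary")
            continue
        ep = baseline_correct(ep)
        ep.is_artifact = is_artifact(ep, threshold_uv)
        if ep.is_artifact:
            yield TrialRecord(i, t, lab, ttype, ep, False, "artifact")
        else:
            yield TrialRecord(i, t, lab, ttype, ep, True)
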