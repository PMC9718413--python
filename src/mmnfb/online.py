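"""Real-time sliding-window MMN estimation.

The online estimator keeps a type-matched FIFO of the most recent accepted
epochs (16 standards, 4 deviants — the 1:4 oddball composition over 20
trials).  Every accepted trial replaces the oldest epoch of the *same*
type and triggers a fresh estimate, so with an 800 ms stimulus onset
asynchrony the MMN value updates every 800 ms.  Artifact epochs never
enter the buffer; the previous estimate simply persists.

Calibration runs the same chain over a tone oddball (1000 Hz standard,
2000 Hz deviant) in batch over all accepted trials and returns the
maximal MMN used to normalize feedback thresholds.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from . import signal_core as sc
from .errors import CalibrationError

N_STANDARD = 16
N_DEVIANT = 4
CALIBRATION_FLOOR_UV = 0.5
"""Minimum usable maximal MMN; below this the calibration is rejected to
guard against division blow-up in threshold normalization."""

DEFAULT_CALIBRATION_TRIALS = 200


@dataclass(frozen=True)
class CalibrationResult:
    """Maximal MMN amplitude (uV) from the tone oddball."""

    max_mmn: float
    n_trials_used: int

    def __post_init__(self):
        if self.max_mmn <= 0:
            raise CalibrationError("maximal MMN must be positive")


class RollingERPBuffer:
    """Type-matched FIFO of accepted epochs with running MMN estimates.

    After warm-up the buffer always holds exactly ``n_standard`` standards
    and ``n_deviant`` deviants, regardless of the artifact pattern.
    """

    def __init__(
        self,
        n_standard: int = N_STANDARD,
        n_deviant: int = N_DEVIANT,
        search_window_ms: tuple[float, float] = sc.MMN_SEARCH_WINDOW_MS,
    ):
        self.standard_fifo: deque[sc.Epoch] = deque(maxlen=n_standard)
        self.deviant_fifo: deque[sc.Epoch] = deque(maxlen=n_deviant)
        self.search_window_ms = search_window_ms
        self._last: sc.MMNEstimate | None = None

    @property
    def warmup_complete(self) -> bool:
        return (
            len(self.standard_fifo) == self.standard_fifo.maxlen
            and len(self.deviant_fifo) == self.deviant_fifo.maxlen
        )

    @property
    def last_estimate(self) -> sc.MMNEstimate | None:
        """Most recent estimate (persists across rejected trials)."""
        return self._last

    def update(self, epoch: sc.Epoch) -> sc.MMNEstimate | None:
        """Insert an accepted, baseline-corrected epoch; return the fresh
        estimate, or ``None`` while still warming up.

        A deque at capacity drops its oldest element on append, which is
        exactly the replace-the-oldest-of-the-same-type rule.
        """
        fifo = self.standard_fifo if epoch.trial_type == "standard" else self.deviant_fifo
        fifo.append(epoch)
        if not self.warmup_complete:
            return None
        est = self._recompute()
        self._last = est
        return est

    def _recompute(self) -> sc.MMNEstimate:
        ep0 = self.standard_fifo[0]
        std = np.mean(np.stack([e.samples for e in self.standard_fifo]), axis=0)
        dev = np.mean(np.stack([e.samples for e in self.deviant_fifo]), axis=0)
        return sc.compute_mmn(
            std, dev, ep0.sample_rate, ep0.pre_ms, self.search_window_ms
        )


@dataclass
class StreamUpdate:
    """One step of the streaming estimator: the trial record and the
    estimate in force after that trial (``None`` during warm-up)."""

    trial: sc.TrialRecord
    estimate: sc.MMNEstimate | None


def stream_session(
    sig: sc.SampledSignal,
    buffer: RollingERPBuffer | None = None,
    threshold_uv: float = sc.ARTIFACT_THRESHOLD_UV,
    band: tuple[float, float] | None = sc.FILTER_BAND_HZ,
    order: int = sc.FILTER_ORDER,
) -> Iterator[StreamUpdate]:
    """Feed a recorded/simulated session through the online estimator.

    Yields one update per event, in time order.  Rejected trials do not
    touch the buffer; the yielded estimate is whatever is currently in
    force (so feedback can always use the latest value).
    """
    buffer = buffer if buffer is not None else RollingERPBuffer()
    for rec in sc.iter_trials(sig, threshold_uv, band, order):
        if rec.accepted:
            buffer.update(rec.epoch)
        yield StreamUpdate(rec, buffer.last_estimate)


def calibrate_max_mmn(
    tone_session: sc.SampledSignal,
    threshold_uv: float = sc.ARTIFACT_THRESHOLD_UV,
    band: tuple[float, float] | None = sc.FILTER_BAND_HZ,
    order: int = sc.FILTER_ORDER,
    floor_uv: float = CALIBRATION_FLOOR_UV,
) -> CalibrationResult:
    """Batch maximal-MMN estimate over *all* accepted tone trials.

    Requires at least the warm-up composition (16 standards, 4 deviants)
    among the accepted epochs; raises :class:`CalibrationError` otherwise,
    or when the amplitude falls below the calibration floor (an unusable
    participant or simulation setting).
    """
    epochs = [r.epoch for r in sc.iter_trials(tone_session, threshold_uv, band, order)
              if r.accepted]
    n_std = sum(1 for e in epochs if e.trial_type == "standard")
    n_dev = sum(1 for e in epochs if e.trial_type == "deviant")
    if n_std < N_STANDARD or n_dev < N_DEVIANT:
        raise CalibrationError(
            f"calibration needs >= {N_STANDARD} standard and {N_DEVIANT} deviant "
            f"accepted trials; got {n_std}/{n_dev}"
        )
    dw = sc.difference_wave(epochs)
    est = sc.compute_mmn(
        np.zeros_like(dw.samples), dw.samples, dw.sample_rate, dw.pre_ms
    )
    if est.amplitude < floor_uv:
        raise CalibrationError(
            f"maximal MMN {est.amplitude:.3f} uV below floor {floor_uv} uV"
        )
    return CalibrationResult(est.amplitude, n_std + n_dev)


def normalize(estimate: sc.MMNEstimate, calibration: CalibrationResult) -> sc.MMNEstimate:
    """Express an amplitude as a fraction of the maximal MMN."""
    if calibration.max_mmn <= 0:
        raise CalibrationError("calibration max_mmn must be positive")
    return sc.MMNEstimate(
        estimate.amplitude,
        estimate.peak_latency_ms,
        estimate.amplitude / calibration.max_mmn,
    )
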