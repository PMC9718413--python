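"""Synthetic-data generators.

Everything the system consumes can be simulated here: oddball EEG with a
controllable deviant negativity, blink artifacts and noise; per-participant
binomial BAD-test responses following the Group x Day logit structure; and
a full four-group cohort run (calibration, three training days of
neurofeedback sessions with genuine or yoked feedback, behavioral blocks,
daily BAD tests).

Amplitude semantics of the EEG generator
----------------------------------------
The evoked waveforms (an N1-P2 complex on every trial, plus a Gaussian
negativity on deviants peaking at ``-mmn_amplitude``) are defined at the
*measurement plane*: the signal after the acquisition band-pass.  The
generator builds that target waveform and pre-equalizes it by the inverse
of the default filter response (FFT division, capped where the filter gain
falls below 1%), so that running the full chain on a noise-free recording
returns exactly the injected amplitude.  This keeps "true amplitude" well
defined regardless of the causal filter's passband ripple and sag, which
would otherwise distort a raw-domain injection by 1-3%.  Noise and blinks
are added in the raw domain and experience the filter normally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import behavior, design, game, online
from . import signal_core as sc
from .errors import ParameterError

# Evoked-response shape parameters (measurement-plane, uV and seconds).
N1_AMPLITUDE_UV = -3.0
N1_LATENCY_S = 0.100
N1_WIDTH_S = 0.020
P2_AMPLITUDE_UV = 4.0
P2_LATENCY_S = 0.200
P2_WIDTH_S = 0.030
MMN_LATENCY_S = 0.170
MMN_WIDTH_S = 0.040

BLINK_AMPLITUDE_UV = 150.0
BLINK_WIDTH_S = 0.060
BLINK_EEG_BLEED = 0.10

LEAD_IN_S = 60.0
"""Silence before the first sound; long enough that the causal filter's
start-up transient is negligible by the first trial."""
TAIL_S = 5.0

_EQUALIZE_MIN_GAIN = 0.01


@dataclass
class ParticipantProfile:
    """Ground-truth parameters of one simulated participant."""

    participant_id: str
    group: str
    random_intercept: float = 0.0
    true_mmn_by_day: dict = field(default_factory=dict)
    max_mmn_true: float = 6.0
    blink_rate_per_min: float = 4.0
    noise_sd: float = 8.0
    sex: str = ""

    @property
    def nf(self) -> str:
        return design.group_nf(self.group)

    @property
    def bt(self) -> str:
        return design.group_bt(self.group)


@dataclass(frozen=True)
class SimCoefficients:
    """Fixed-effect vector of the Group x Day binomial model (dummy
    coding, reference NTBT/pre) used to simulate behavioral responses."""

    beta: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.beta, dtype=float)
        if b.shape != (design.N_COEF,) or not np.all(np.isfinite(b)):
            raise ParameterError(f"beta must be {design.N_COEF} finite values")
        object.__setattr__(self, "beta", b)

    @classmethod
    def reference(cls) -> "SimCoefficients":
        """The coefficient set reported for the original cohort."""
        return cls(design.REFERENCE_BETA.copy())

    @classmethod
    def null(cls) -> "SimCoefficients":
        """All effects zero: 50% correct everywhere."""
        return cls(np.zeros(design.N_COEF))

    def cell_probability(self, group: str, day: str, u: float = 0.0) -> float:
        return float(design.logistic(design.cell_logit(self.beta, group, day, u)))


def generate_oddball_sequence(
    n_sounds: int = 300,
    ratio: tuple[int, int] = (1, 4),
    seed: int | np.random.Generator = 0,
    labels: tuple[str, str] = ("standard", "deviant"),
) -> list[str]:
    """Seeded oddball label sequence with no two consecutive deviants.

    ``ratio`` is deviant:standard (1:4 gives 60 deviants per 300 sounds).
    Deviant positions are drawn uniformly over all non-adjacent subsets via
    the standard gap construction.
    """
    d, s = ratio
    unit = d + s
    if n_sounds % unit:
        raise ParameterError(f"n_sounds must divide into the {d}:{s} ratio")
    n_dev = n_sounds // unit * d
    if n_dev > (n_sounds + 1) // 2:
        raise ParameterError("too many deviants for the no-adjacency constraint")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # choosing k non-adjacent slots from n == choosing k from n-k+1 and spreading
    pos = np.sort(rng.choice(n_sounds - n_dev + 1, size=n_dev, replace=False))
    pos = pos + np.arange(n_dev)
    seq = [labels[0]] * n_sounds
    for p in pos:
        seq[p] = labels[1]
    return seq


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _templates(sample_rate: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Standard-evoked and unit-MMN templates on a [-0.1, 0.45) s grid."""
    n_pre = int(round(0.1 * sample_rate))
    n_post = int(round(0.45 * sample_rate))
    t = (np.arange(-n_pre, n_post)) / sample_rate
    std = N1_AMPLITUDE_UV * _gauss(t, N1_LATENCY_S, N1_WIDTH_S) + \
        P2_AMPLITUDE_UV * _gauss(t, P2_LATENCY_S, P2_WIDTH_S)
    mmn = -_gauss(t, MMN_LATENCY_S, MMN_WIDTH_S)
    return std, mmn, n_pre


def _equalize(y: np.ndarray, sample_rate: float, band, order) -> np.ndarray:
    """Raw signal whose band-passed version reproduces ``y`` (up to an
    additive constant and ultra-low-frequency content below the gain cap,
    both removed by baseline correction)."""
    sos = sc.design_bandpass(band[0], band[1], sample_rate, order)
    n = y.shape[0]
    spec = np.fft.rfft(y - y.mean())
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    _, resp = sps.sosfreqz(sos, worN=freqs, fs=sample_rate)
    out = spec.copy()
    ok = np.abs(resp) >= _EQUALIZE_MIN_GAIN
    out[ok] = spec[ok] / resp[ok]
    out[0] = 0.0
    return np.fft.irfft(out, n)


def _band_limited_noise(rng, n, sample_rate, sd):
    """Low-passed Gaussian noise rescaled to the requested SD."""
    white = rng.standard_normal(n)
    sos = sps.butter(2, 45.0, btype="low", fs=sample_rate, output="sos")
    x = sps.sosfilt(sos, white)
    return x * (sd / np.std(x))


def synthesize_eeg(
    sequence: Sequence[str],
    mmn_amplitude: float,
    profile: ParticipantProfile | None = None,
    seed: int | np.random.Generator = 0,
    sample_rate: float = sc.DEFAULT_SAMPLE_RATE,
    soa_ms: float = 800.0,
    noise_sd: float | None = None,
    blink_rate_per_min: float | None = None,
    band: tuple[float, float] = sc.FILTER_BAND_HZ,
    order: int = sc.FILTER_ORDER,
    lead_in_s: float = LEAD_IN_S,
) -> sc.SampledSignal:
    """Simulated continuous oddball recording (EEG + EOG with markers).

    Every sound evokes the N1-P2 complex; deviants additionally evoke the
    Gaussian negativity with measurement-plane peak ``-mmn_amplitude``.
    ``noise_sd`` (uV, raw domain) and ``blink_rate_per_min`` default to the
    profile's values, or to 0 when no profile is given.
    """
    if mmn_amplitude < 0:
        raise ParameterError("mmn_amplitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = profile.noise_sd if profile is not None else 0.0
    if blink_rate_per_min is None:
        blink_rate_per_min = profile.blink_rate_per_min if profile is not None else 0.0

    soa_s = soa_ms / 1000.0
    n_sounds = len(sequence)
    total_s = lead_in_s + n_sounds * soa_s + TAIL_S
    n = int(round(total_s * sample_rate))

    std_tpl, mmn_tpl, tpl_pre = _templates(sample_rate)
    onset_idx = (lead_in_s + np.arange(n_sounds) * soa_s) * sample_rate
    onset_idx = np.round(onset_idx).astype(int)
    is_dev = np.array([sc.canonical_trial_type(lab) == "deviant" for lab in sequence])

    target = np.zeros(n)
    span = np.arange(-tpl_pre, std_tpl.shape[0] - tpl_pre)
    idx = onset_idx[:, None] + span[None, :]
    np.add.at(target, idx, std_tpl[None, :])
    if is_dev.any() and mmn_amplitude > 0:
        np.add.at(target, idx[is_dev], mmn_amplitude * mmn_tpl[None, :])

    eeg = _equalize(target, sample_rate, band, order)
    eog = np.zeros(n)

    if noise_sd > 0:
        eeg = eeg + _band_limited_noise(rng, n, sample_rate, noise_sd)
        eog = eog + _band_limited_noise(rng, n, sample_rate, 0.5 * noise_sd)
    if blink_rate_per_min > 0:
        active_s = n_sounds * soa_s
        n_blinks = rng.poisson(blink_rate_per_min * active_s / 60.0)
        times = lead_in_s + rng.uniform(0.0, active_s, size=n_blinks)
        t_axis = np.arange(n) / sample_rate
        for tb in times:
            m = (t_axis > tb - 5 * BLINK_WIDTH_S) & (t_axis < tb + 5 * BLINK_WIDTH_S)
            pulse = BLINK_AMPLITUDE_UV * _gauss(t_axis[m], tb, BLINK_WIDTH_S)
            eog[m] += pulse
            eeg[m] += BLINK_EEG_BLEED * pulse

    events = tuple(
        (oi * 1000.0 / sample_rate, lab) for oi, lab in zip(onset_idx, sequence)
    )
    return sc.SampledSignal(sample_rate, eeg, eog, events)


def synthesize_tone_calibration(
    profile: ParticipantProfile,
    n_trials: int = online.DEFAULT_CALIBRATION_TRIALS,
    seed: int | np.random.Generator = 0,
    **kwargs,
) -> sc.SampledSignal:
    """Tone oddball (1000 Hz standard / 2000 Hz deviant roles) whose
    deviant negativity equals the participant's true maximal MMN."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = generate_oddball_sequence(n_trials, seed=rng, labels=("tone_std", "tone_dev"))
    return synthesize_eeg(seq, profile.max_mmn_true, profile, rng, **kwargs)


# ---------------------------------------------------------------------------
# behavioral simulation

# Default normalized MMN trajectory (fraction of the maximal MMN) across
# training days: genuine neurofeedback grows linearly, sham stays flat.
GENUINE_MMN_FRACTIONS = {"d1": 0.45, "d2": 0.55, "d3": 0.65}
SHAM_MMN_FRACTIONS = {"d1": 0.45, "d2": 0.45, "d3": 0.45}


def make_profiles(
    seed: int | np.random.Generator = 0,
    n_per_group: int = 8,
    sigma_u: float = design.REFERENCE_SIGMA_U,
    max_mmn_mean: float = 6.0,
    max_mmn_sd: float = 1.0,
    noise_sd: float = 8.0,
    blink_rate_per_min: float = 4.0,
) -> list[ParticipantProfile]:
    """Cohort of ``4 * n_per_group`` participants, half of each recorded
    sex per group (metadata only)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profiles = []
    pid = 0
    for group in design.GROUPS:
        fr = GENUINE_MMN_FRACTIONS if design.group_nf(group) == "genuine" \
            else SHAM_MMN_FRACTIONS
        for k in range(n_per_group):
            pid += 1
            mx = float(np.clip(rng.normal(max_mmn_mean, max_mmn_sd),
                               max_mmn_mean - 2 * max_mmn_sd,
                               max_mmn_mean + 2 * max_mmn_sd))
            profiles.append(ParticipantProfile(
                participant_id=f"P{pid:02d}",
                group=group,
                random_intercept=float(rng.normal(0.0, sigma_u)),
                true_mmn_by_day={d: f * mx for d, f in fr.items()},
                max_mmn_true=mx,
                blink_rate_per_min=blink_rate_per_min,
                noise_sd=noise_sd,
                sex="F" if k < n_per_group / 2 else "M",
            ))
    return profiles


def simulate_behavioral_responses(
    profile: ParticipantProfile,
    day: str,
    coefficients: SimCoefficients | None = None,
    n_trials: int = 96,
    seed: int | np.random.Generator = 0,
) -> list[behavior.BADTrial]:
    """Trial-level BAD responses: correct ~ Bernoulli(p) with
    logit(p) = x(group, day) . beta + random intercept."""
    coefficients = coefficients or SimCoefficients.reference()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = coefficients.cell_probability(profile.group, day, profile.random_intercept)
    trials = behavior.generate_bad_sequence(int(rng.integers(2**31)), n_trials)
    return behavior.run_bad_test(trials, behavior.bernoulli_responder(p, rng))


def simulate_bad_counts(
    coefficients: SimCoefficients | None = None,
    profiles: Sequence[ParticipantProfile] | None = None,
    days: Sequence[str] = design.DAYS,
    n_trials: int = 96,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Correct/incorrect counts per participant x day.

    Counts are drawn binomially from the cell probability, which is
    exactly the distribution of the trial-level path aggregated.
    """
    coefficients = coefficients or SimCoefficients.reference()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if profiles is None:
        profiles = make_profiles(rng)
    rows = []
    for pr in profiles:
        for day in days:
            p = coefficients.cell_probability(pr.group, day, pr.random_intercept)
            k = int(rng.binomial(n_trials, p))
            rows.append({
                "participant": pr.participant_id, "group": pr.group, "day": day,
                "n_correct": k, "n_incorrect": n_trials - k,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full experiment

@dataclass(frozen=True)
class ExperimentConfig:
    """Sizes and parameters of a simulated cohort run.

    Defaults are the study conditions: 8 participants per group, 12
    sessions of 300 sounds per training day, 96 BAD trials per day, a
    200-trial tone calibration before training.
    """

    n_per_group: int = 8
    n_bad_trials: int = 96
    calibration_trials: int = online.DEFAULT_CALIBRATION_TRIALS
    game: game.GameConfig = field(default_factory=game.GameConfig)
    noise_sd: float = 8.0
    blink_rate_per_min: float = 4.0
    keep_trial_logs: bool = False


@dataclass
class ExperimentDataset:
    """In-memory result tables of one simulated experiment."""

    profiles: pd.DataFrame
    calibration: pd.DataFrame
    bad_counts: pd.DataFrame
    bad_trials: pd.DataFrame
    mmn_normalized: pd.DataFrame
    sessions: pd.DataFrame
    training_summary: pd.DataFrame
    manifest: dict
    trial_logs: pd.DataFrame | None = None


def _run_nf_session(sig, calibration):
    """Stream one session; return (estimate stream, per-session batch MMN,
    rejection count)."""
    stream = []
    epochs = []
    n_rej = 0
    for upd in online.stream_session(sig):
        stream.append(upd.estimate)
        if upd.trial.accepted:
            epochs.append(upd.trial.epoch)
        elif upd.trial.reason == "artifact":
            n_rej += 1
    dw = sc.difference_wave(epochs)
    batch = sc.compute_mmn(np.zeros_like(dw.samples), dw.samples,
                           dw.sample_rate, dw.pre_ms)
    return stream, batch, n_rej


def simulate_experiment(
    config: ExperimentConfig | None = None, seed: int = 0
) -> ExperimentDataset:
    """Run the full protocol for the whole cohort.

    Genuine-NF participants (NT groups) play on their own MMN stream; each
    sham participant (NC groups) is yoked to a genuine donor and replays
    the donor's recorded estimate streams, so sham game progress is
    uncorrelated with the player's own brain activity.  Behavioral
    training runs daily with feedback only for *BT groups; the BAD test
    runs at pre and after each training day.
    """
    config = config or ExperimentConfig()
    rng = np.random.default_rng(seed)
    gcfg = config.game
    profiles = make_profiles(rng, config.n_per_group,
                             noise_sd=config.noise_sd,
                             blink_rate_per_min=config.blink_rate_per_min)
    coefficients = SimCoefficients.reference()

    genuine = [p for p in profiles if p.nf == "genuine"]
    sham = [p for p in profiles if p.nf == "sham"]
    donor_of = {s.participant_id: genuine[i % len(genuine)].participant_id
                for i, s in enumerate(sham)}

    calib_rows, session_rows, mmn_rows, trial_log_rows = [], [], [], []
    bad_count_rows, bad_trial_rows, training_rows = [], [], []
    calibrations: dict[str, online.CalibrationResult] = {}
    donor_streams: dict[tuple, list] = {}

    for idx, pr in enumerate(profiles):  # genuine first by construction
        sig = synthesize_tone_calibration(pr, config.calibration_trials, rng)
        cal = online.calibrate_max_mmn(sig)
        calibrations[pr.participant_id] = cal
        calib_rows.append({"participant": pr.participant_id, "group": pr.group,
                           "max_mmn": cal.max_mmn, "true_max_mmn": pr.max_mmn_true,
                           "n_trials_used": cal.n_trials_used})

        for di, day in enumerate(design.TRAINING_DAYS):
            plan = game.plan_training_day(idx, di, gcfg)
            state = game.StageState()
            day_amps = []
            for si, sp in enumerate(plan.sessions):
                seq = generate_oddball_sequence(sp.n_sounds, seed=rng)
                sig = synthesize_eeg(seq, pr.true_mmn_by_day[day], pr, rng,
                                     soa_ms=sp.soa_ms)
                stream, batch, n_rej = _run_nf_session(sig, cal)
                norm_stream = [None if e is None else online.normalize(e, cal)
                               for e in stream]
                if pr.nf == "genuine":
                    donor_streams[(pr.participant_id, day, si)] = norm_stream
                    source = game.FeedbackSource("genuine")
                    played = norm_stream
                else:
                    donor = donor_of[pr.participant_id]
                    played = donor_streams[(donor, day, si)]
                    source = game.FeedbackSource("yoked", donor_stream=played)
                res = game.run_session(norm_stream, state, cal, gcfg, source)
                state = res.state
                day_amps.append(batch.amplitude)
                session_rows.append({
                    "participant": pr.participant_id, "group": pr.group,
                    "day": day, "session": si, "game": sp.game,
                    "mode": pr.nf, "n_sounds": sp.n_sounds,
                    "n_rejected": n_rej,
                    "n_attempts": len(res.attempts),
                    "n_success": sum(a.success for a in res.attempts),
                    "final_stage": state.stage_index,
                    "batch_mmn_uv": batch.amplitude,
                })
                if config.keep_trial_logs:
                    for ti, (lab, est) in enumerate(zip(seq, norm_stream)):
                        trial_log_rows.append({
                            "participant": pr.participant_id, "day": day,
                            "session": si, "trial_index": ti, "event_label": lab,
                            "mmn_uV": None if est is None else est.amplitude,
                            "normalized": None if est is None else est.normalized,
                        })
            mmn_rows.append({
                "participant": pr.participant_id, "group": pr.group,
                "nf": pr.nf, "bt": pr.bt, "day": day,
                "value": float(np.mean(day_amps)) / cal.max_mmn,
            })

            trials = behavior.generate_training_sequence(int(rng.integers(2**31)))
            p = coefficients.cell_probability(pr.group, day, pr.random_intercept)
            behavior.run_training_block(trials, pr.bt == "feedback",
                                        behavior.bernoulli_responder(p, rng))
            training_rows.append({
                "participant": pr.participant_id, "group": pr.group, "day": day,
                "feedback": pr.bt == "feedback",
                "n_correct": sum(bool(t.correct) for t in trials),
                "n_trials": len(trials),
            })

        for day in design.DAYS:
            trials = simulate_behavioral_responses(
                pr, day, coefficients, config.n_bad_trials, rng)
            score = behavior.score_bad(trials)
            bad_count_rows.append({
                "participant": pr.participant_id, "group": pr.group, "day": day,
                "n_correct": score.n_correct, "n_incorrect": score.n_incorrect,
            })
            for ti, t in enumerate(trials):
                bad_trial_rows.append({
                    "participant": pr.participant_id, "group": pr.group,
                    "day": day, "trial_index": ti, "first": t.first,
                    "second": t.second, "response": t.response,
                    "correct": t.correct,
                })

    prof_df = pd.DataFrame([{
        "participant": p.participant_id, "group": p.group, "nf": p.nf,
        "bt": p.bt, "sex": p.sex, "random_intercept": p.random_intercept,
        "max_mmn_true": p.max_mmn_true, "noise_sd": p.noise_sd,
        "blink_rate_per_min": p.blink_rate_per_min,
    } for p in profiles])
    manifest = {
        "seed": seed,
        "n_participants": len(profiles),
        "config": {
            "n_per_group": config.n_per_group,
            "n_bad_trials": config.n_bad_trials,
            "calibration_trials": config.calibration_trials,
            "noise_sd": config.noise_sd,
            "blink_rate_per_min": config.blink_rate_per_min,
            "sounds_per_session": gcfg.sounds_per_session,
            "soa_ms": gcfg.soa_ms,
            "sessions_per_day": gcfg.sessions_per_day,
        },
        "yoked_donors": donor_of,
    }
    return ExperimentDataset(
        profiles=prof_df,
        calibration=pd.DataFrame(calib_rows),
        bad_counts=pd.DataFrame(bad_count_rows),
        bad_trials=pd.DataFrame(bad_trial_rows),
        mmn_normalized=pd.DataFrame(mmn_rows),
        sessions=pd.DataFrame(session_rows),
        training_summary=pd.DataFrame(training_rows),
        manifest=manifest,
        trial_logs=pd.DataFrame(trial_log_rows) if config.keep_trial_logs else None,
    )
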