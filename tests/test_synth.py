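"""Synthetic-data generators: sequences, EEG round trips, behavioral logit."""

import numpy as np
import pytest
from scipy import signal as sps

from mmnfb import behavior, design, game, online, synth
from mmnfb import signal_core as sc
from mmnfb.errors import ParameterError


class TestOddballSequence:
    def test_counts_and_no_adjacent_deviants(self):
        seq = synth.generate_oddball_sequence(300, seed=0)
        assert seq.count("standard") == 240 and seq.count("deviant") == 60
        assert not any(a == b == "deviant" for a, b in zip(seq, seq[1:]))

    def test_seeded_determinism(self):
        assert synth.generate_oddball_sequence(300, seed=3) == \
               synth.generate_oddball_sequence(300, seed=3)
        assert synth.generate_oddball_sequence(300, seed=3) != \
               synth.generate_oddball_sequence(300, seed=4)

    def test_invalid_length(self):
        with pytest.raises(ParameterError):
            synth.generate_oddball_sequence(301, seed=0)


class TestEEGSynthesis:
    def test_noise_free_round_trip(self):
        seq = synth.generate_oddball_sequence(300, seed=1)
        sig = synth.synthesize_eeg(seq, 5.0, seed=1)
        cal = online.calibrate_max_mmn(sig, floor_uv=0.0)
        assert cal.max_mmn == pytest.approx(5.0, abs=1e-3)

    def test_zero_amplitude_consistent_with_windowed_minimum_null(self):
        """With no deviant response the chain should recover only the
        noise floor of the windowed minimum.  The null distribution is
        simulated directly from matched band-limited noise averages."""
        n_std, n_dev, noise_sd = 80, 20, 8.0
        sos = sc.design_bandpass()
        rng = np.random.default_rng(123)
        null = []
        for _ in range(200):
            segs = []
            for count in (n_std, n_dev):
                raw = synth._band_limited_noise(rng, count * 300, 500.0, noise_sd)
                eps = sps.sosfilt(sos, raw).reshape(count, 300)
                eps = eps - eps[:, :50].mean(axis=1, keepdims=True)
                segs.append(eps.mean(axis=0))
            null.append(sc.compute_mmn(segs[0], segs[1]).amplitude)
        mu0, sd0 = float(np.mean(null)), float(np.std(null))

        chain = []
        for s in range(50):
            seq = synth.generate_oddball_sequence(100, seed=s)
            prof = synth.ParticipantProfile("x", "NTBT", noise_sd=noise_sd,
                                            blink_rate_per_min=0.0)
            sig = synth.synthesize_eeg(seq, 0.0, prof, seed=s)
            eps = [r.epoch for r in sc.iter_trials(sig) if r.accepted]
            dw = sc.difference_wave(eps)
            chain.append(sc.compute_mmn(np.zeros_like(dw.samples), dw.samples,
                                        dw.sample_rate, dw.pre_ms).amplitude)
        mean_chain = float(np.mean(chain))
        # two-sample 3-sigma consistency with the null oracle
        tol = 3.0 * sd0 * np.sqrt(1 / 50 + 1 / 200)
        assert abs(mean_chain - mu0) < tol
        assert mean_chain < mu0 + 3.0 * sd0

    def test_blinks_rejected_without_biasing_estimate(self):
        seq = synth.generate_oddball_sequence(300, seed=3)

        def run(blink_rate):
            sig = synth.synthesize_eeg(seq, 5.0, seed=3, noise_sd=0.0,
                                       blink_rate_per_min=blink_rate)
            n_rej = 0
            eps = []
            for r in sc.iter_trials(sig):
                if r.accepted:
                    eps.append(r.epoch)
                elif r.reason == "artifact":
                    n_rej += 1
            dw = sc.difference_wave(eps)
            est = sc.compute_mmn(np.zeros_like(dw.samples), dw.samples,
                                 dw.sample_rate, dw.pre_ms)
            return est.amplitude, n_rej

        clean_amp, clean_rej = run(0.0)
        blink_amp, blink_rej = run(15.0)
        assert clean_rej == 0 and blink_rej > 0
        assert blink_amp == pytest.approx(clean_amp, abs=0.1)

    def test_eog_blink_amplitude_and_bleed(self):
        seq = synth.generate_oddball_sequence(100, seed=4)
        sig = synth.synthesize_eeg(seq, 0.0, seed=4, noise_sd=0.0,
                                   blink_rate_per_min=20.0)
        assert sig.eog.max() > 100.0           # blinks on the EOG channel
        i = int(np.argmax(sig.eog))
        assert sig.eeg[i] == pytest.approx(0.1 * sig.eog[i], abs=1.0)


class TestBehavioralSimulation:
    def test_reference_intercept_probability(self):
        """logit(p) = 0.0892 for the reference cell: p ~ 0.5223."""
        prof = synth.ParticipantProfile("x", "NTBT", random_intercept=0.0)
        tbl = synth.simulate_bad_counts(synth.SimCoefficients.reference(),
                                        [prof], days=("pre",),
                                        n_trials=100_000, seed=0)
        phat = tbl["n_correct"].iloc[0] / 100_000
        expected = float(design.logistic(0.0892))
        assert phat == pytest.approx(expected, abs=0.01)

    def test_trial_level_matches_counts_level(self):
        prof = synth.ParticipantProfile("x", "NCBC", random_intercept=0.05)
        coef = synth.SimCoefficients.reference()
        props = []
        for s in range(100):
            trials = synth.simulate_behavioral_responses(prof, "d2", coef,
                                                         seed=s)
            props.append(behavior.score_bad(trials).proportion)
        expected = coef.cell_probability("NCBC", "d2", 0.05)
        assert np.mean(props) == pytest.approx(expected, abs=0.015)

    def test_null_coefficients_give_chance(self):
        prof = synth.ParticipantProfile("x", "NTBT")
        tbl = synth.simulate_bad_counts(synth.SimCoefficients.null(), [prof],
                                        days=("pre",), n_trials=100_000, seed=1)
        assert tbl["n_correct"].iloc[0] / 100_000 == pytest.approx(0.5, abs=0.01)

    def test_intercept_shift_raises_every_cell(self):
        coef = synth.SimCoefficients.reference()
        shifted = synth.SimCoefficients(coef.beta + np.eye(design.N_COEF)[0])
        for g in design.GROUPS:
            for d in design.DAYS:
                assert shifted.cell_probability(g, d) > coef.cell_probability(g, d)


class TestCohortSimulation:
    def test_profiles_structure(self):
        profiles = synth.make_profiles(0)
        assert len(profiles) == 32
        for g in design.GROUPS:
            sub = [p for p in profiles if p.group == g]
            assert len(sub) == 8
            assert sum(1 for p in sub if p.sex == "F") == 4

    def test_scaled_experiment_structure_and_mmn_trajectory(self):
        cfg = synth.ExperimentConfig(
            n_per_group=2, calibration_trials=100,
            game=game.GameConfig(sounds_per_session=200, attempts_per_stage=5,
                                 sessions_per_game_per_day=2))
        ds = synth.simulate_experiment(cfg, seed=0)
        assert ds.profiles.shape[0] == 8
        # BAD totals: n_bad_trials per participant-day, all four days
        counts = ds.bad_counts
        assert (counts["n_correct"] + counts["n_incorrect"]).eq(96).all()
        assert counts.shape[0] == 8 * 4
        # sessions: 3 games x 2 sessions per day per participant
        per_day = ds.sessions.groupby(["participant", "day"]).size()
        assert (per_day == 6).all()
        # sham feedback is donor-driven
        assert set(ds.manifest["yoked_donors"]) == \
               set(ds.profiles[ds.profiles.nf == "sham"].participant)
        # simulator's own output shows the trained groups' MMN growth
        mmn = ds.mmn_normalized
        genuine = mmn[mmn.nf == "genuine"].groupby("day")["value"].mean()
        assert genuine["d3"] > genuine["d1"]

    def test_training_summary_feedback_assignment(self):
        cfg = synth.ExperimentConfig(
            n_per_group=1, calibration_trials=50,
            game=game.GameConfig(sounds_per_session=100, attempts_per_stage=5,
                                 sessions_per_game_per_day=1))
        ds = synth.simulate_experiment(cfg, seed=1)
        merged = ds.training_summary.merge(ds.profiles, on="participant")
        assert (merged["feedback"] == (merged["bt"] == "feedback")).all()
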