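"""Real-time sliding-window MMN estimation with calibration.

First calibrates the maximal MMN from a tone oddball (1000/2000 Hz
roles), then streams a word-oddball session through the online estimator:
no estimate until 16 standards + 4 deviants have been accepted, then a
fresh value every trial (i.e. every 800 ms), each new epoch replacing the
oldest of its own type.
"""

from mmnfb import online, synth

profile = synth.ParticipantProfile("demo", "NTBT", max_mmn_true=6.0,
                                   noise_sd=6.0, blink_rate_per_min=4.0)

cal = online.calibrate_max_mmn(synth.synthesize_tone_calibration(profile, 200, 1))
print(f"maximal MMN from the tone oddball: {cal.max_mmn:.2f} uV "
      f"({cal.n_trials_used} accepted trials; true value 6.00 uV)")

seq = synth.generate_oddball_sequence(300, seed=2)
sig = synth.synthesize_eeg(seq, mmn_amplitude=3.0, profile=profile, seed=2)

warmup_end = None
for i, upd in enumerate(online.stream_session(sig)):
    if upd.estimate is None:
        continue
    if warmup_end is None:
        warmup_end = i
        print(f"warm-up complete after trial {i + 1}")
    if (i + 1) % 60 == 0:
        norm = online.normalize(upd.estimate, cal)
        print(f"  trial {i + 1:3d}: MMN {norm.amplitude:4.2f} uV "
              f"= {norm.normalized:.0%} of maximal "
              f"(peak at {norm.peak_latency_ms:.0f} ms)")
print("the normalized fraction is what the game compares against its "
      "stage thresholds")
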