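"""Batch ERP signal chain on one simulated oddball session.

Synthesizes a 300-sound oddball recording (800 ms SOA, 4:1
standard:deviant) with a 4 uV deviant negativity, realistic noise and
blinks, then runs filter -> epoch -> baseline -> artifact gate ->
averaging -> peak scoring and prints what each stage produced.
"""

import numpy as np

from mmnfb import signal_core as sc
from mmnfb import synth

seq = synth.generate_oddball_sequence(300, seed=0)
profile = synth.ParticipantProfile("demo", "NTBT", noise_sd=8.0,
                                   blink_rate_per_min=4.0)
sig = synth.synthesize_eeg(seq, mmn_amplitude=4.0, profile=profile, seed=0)
print(f"recording: {sig.n_samples} samples at {sig.sample_rate:g} Hz, "
      f"{len(sig.events)} stimulus events")

epochs, n_rejected = [], 0
for rec in sc.iter_trials(sig):
    if rec.accepted:
        epochs.append(rec.epoch)
    else:
        n_rejected += 1
print(f"epochs: {len(epochs)} accepted, {n_rejected} rejected "
      f"(artifact gate at +-{sc.ARTIFACT_THRESHOLD_UV:g} uV)")

dw = sc.difference_wave(epochs)
est = sc.compute_mmn(np.zeros_like(dw.samples), dw.samples,
                     dw.sample_rate, dw.pre_ms)
print(f"difference wave over {dw.n_standard} standards / {dw.n_deviant} deviants")
print(f"MMN amplitude {est.amplitude:.2f} uV at {est.peak_latency_ms:.0f} ms "
      f"(injected 4.00 uV at 170 ms; averaging noise and the windowed-minimum "
      f"bias explain the gap)")
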