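# File formats

All files are UTF-8, comma-separated CSV with a header row and "." decimal
separator, or JSON. Times are milliseconds, amplitudes microvolts.

## Continuous recordings

- data CSV: `time_ms, eeg_uV, eog_uV` — uniform sample times (rate inferred
  from the spacing).
- events CSV: `time_ms, label` with labels from
  `{standard, deviant, tone_std, tone_dev}`; event times must lie inside
  the recording.
- EDF input is optionally supported through `mmnfb.io.read_edf` when `mne`
  is installed (channels in file order as EEG, EOG; annotations as events).

## Epoch dumps

`io.write_epoch_csv` writes one epoch with a first column whose header
names the span and trial type, e.g. `time_ms[-100..498](deviant)`, plus
`eeg_uV, eog_uV`.

## Simulated dataset directory (`mmnfb simulate --out DIR`)

| file | columns |
|---|---|
| `profiles.csv` | participant, group, nf, bt, sex, random_intercept, max_mmn_true, noise_sd, blink_rate_per_min |
| `calibration.csv` | participant, group, max_mmn, true_max_mmn, n_trials_used |
| `bad_counts.csv` | participant, group, day, n_correct, n_incorrect |
| `bad_trials.csv` | participant, group, day, trial_index, first, second, response, correct |
| `mmn_normalized.csv` | participant, group, nf, bt, day, value |
| `sessions.csv` | participant, group, day, session, game, mode, n_sounds, n_rejected, n_attempts, n_success, final_stage, batch_mmn_uv |
| `training_summary.csv` | participant, group, day, feedback, n_correct, n_trials |
| `trial_logs.csv` (optional) | participant, day, session, trial_index, event_label, mmn_uV, normalized |
| `config.json` | the resolved `RunConfig` (seed and every module parameter block) |
| `manifest.json` | seed, sizes, yoked donor map, SHA-256 checksums of all files |

`bad_counts.csv` is the input contract of `stats.fit_mixed_logit`;
`mmn_normalized.csv` is the input contract of `stats.mixed_anova`.
`mmnfb selftest --dataset DIR` re-verifies the checksums.

## Analysis report (`mmnfb analyze`)

`report.json` holds the 16 fixed effects with SEs, σ_u, log-likelihood,
the type III Wald table, Tukey-adjusted group contrasts per day and day
contrasts per group (as odds ratios), and the ANOVA tables (omnibus,
simple main effects, LSD). `report.md` is the human-readable rendering.
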