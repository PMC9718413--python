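"""One neurofeedback training day: genuine versus yoked-sham feedback.

Plays 12 sessions (3 games x 4 sessions, Latin-square game order) for a
genuine participant whose MMN amplitude sits around stage-2/3 thresholds,
then replays the same day for a yoked participant whose game is driven by
the genuine player's recorded estimates.
"""

import numpy as np

from mmnfb import game, online
from mmnfb.signal_core import MMNEstimate

cal = online.CalibrationResult(max_mmn=6.0, n_trials_used=200)
cfg = game.GameConfig()
rng = np.random.default_rng(0)

plan = game.plan_training_day(participant_seed=0, config=cfg)
print(f"game order today: {' -> '.join(plan.game_order)} "
      f"(4 x {cfg.session_duration_s:.0f} s sessions each)")


def play_day(label, live_streams, source):
    state = game.StageState()
    for si, sp in enumerate(plan.sessions):
        res = game.run_session(live_streams[si], state, cal, cfg, source)
        state = res.state
        if si % 4 == 3:
            n_ok = sum(a.success for a in res.attempts)
            print(f"  [{label}] session {si + 1:2d} ({sp.game}): "
                  f"{n_ok}/{len(res.attempts)} targets hit, "
                  f"now at stage {state.stage_index}")
    return state


# genuine day: amplitudes drawn around 45% of the maximal MMN
streams = [[MMNEstimate(a, 170.0) for a in rng.normal(2.7, 1.0, 300).clip(0)]
           for _ in plan.sessions]
final = play_day("genuine", streams, game.FeedbackSource("genuine"))
print(f"genuine player finished the day at stage {final.stage_index}")

# yoked day: the sham player's own (here: zero) MMN is never consulted
own = [[MMNEstimate(0.0, 170.0)] * 300 for _ in plan.sessions]
for si in range(len(plan.sessions)):
    src = game.FeedbackSource("yoked", donor_stream=streams[si])
    state = game.run_session(own[si], game.StageState(), cal, cfg, src)
print("yoked player saw the donor's hits and misses regardless of their "
      "own brain activity — the sham severs the feedback contingency")
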