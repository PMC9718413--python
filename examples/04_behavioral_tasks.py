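"""The two behavioral paradigms with a simulated responder.

Runs the 96-trial same/different auditory discrimination (BAD) test and
the 96-trial 2AFC identification training (with and without feedback)
for a responder of fixed 70% accuracy.
"""

import numpy as np

from mmnfb import behavior

rng = np.random.default_rng(0)
responder = behavior.bernoulli_responder(0.7, rng)

trials = behavior.run_bad_test(behavior.generate_bad_sequence(seed=1), responder)
score = behavior.score_bad(trials)
print(f"BAD test: {score.n_correct}/96 correct "
      f"({score.proportion:.1%}; chance is 50% — half the pairs differ)")

for feedback_on in (True, False):
    block = behavior.run_training_block(
        behavior.generate_training_sequence(seed=2), feedback_on, responder)
    n_ok = sum(bool(t.correct) for t in block)
    chimes = sum(t.feedback == "chime" for t in block)
    buzzers = sum(t.feedback == "buzzer" for t in block)
    print(f"2AFC training ({'with' if feedback_on else 'no'} feedback): "
          f"{n_ok}/96 correct, {chimes} chimes, {buzzers} buzzers")
print("in the control condition the same task runs silently: the "
      "correct/incorrect counts are what the group analysis consumes")
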