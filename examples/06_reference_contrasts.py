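"""Published odds ratios from the reference coefficient table.

Wraps the 16 fixed-effect estimates reported for the original cohort and
exponentiates pairwise cell contrasts of the dummy-coded Group x Day
model — the same computation scripts/acceptance.py reports.
"""

from mmnfb import design, stats

fit = stats.MixedLogitFit.from_estimates(design.REFERENCE_BETA,
                                         sigma_u=design.REFERENCE_SIGMA_U)

print("group contrasts on each day (OR of the first group vs the second):")
for day in design.DAYS:
    ors = [f"{a} vs {b}: "
           f"{stats.odds_ratio_from_fit(fit, (a, day), (b, day)).odds_ratio:5.3f}"
           for a, b in [("NTBT", "NTBC"), ("NTBT", "NCBC"), ("NCBT", "NCBC")]]
    print(f"  {day:3s}  " + "   ".join(ors))

print("\nday contrasts within each group (pre vs later days; OR < 1 means")
print("the later day had higher odds of a correct answer):")
for group in design.GROUPS:
    ors = [f"pre vs {d}: "
           f"{stats.odds_ratio_from_fit(fit, (group, 'pre'), (group, d)).odds_ratio:5.3f}"
           for d in design.TRAINING_DAYS]
    print(f"  {group}  " + "   ".join(ors))
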