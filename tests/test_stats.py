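"""Statistics: GLMM fit, Wald tests, odds-ratio contrasts, mixed ANOVA."""

import itertools
import json
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from mmnfb import design, stats, synth
from mmnfb.errors import ParameterError


def _simulate_counts(seed, n_per_group=8, n_trials=96, coefficients=None):
    rng = np.random.default_rng(seed)
    prof = synth.make_profiles(rng, n_per_group=n_per_group)
    return synth.simulate_bad_counts(coefficients, prof, n_trials=n_trials,
                                     seed=rng)


class TestMixedLogitFit:
    def test_large_sample_no_random_effect_recovers_cell_logits(self):
        """With sigma_u = 0 and many trials the fit collapses to the
        empirical cell logits (the closed-form GLM solution)."""
        rng = np.random.default_rng(11)
        prof = synth.make_profiles(rng, n_per_group=4, sigma_u=0.0)
        tbl = synth.simulate_bad_counts(synth.SimCoefficients.reference(),
                                        prof, n_trials=5000, seed=rng)
        fit = stats.fit_mixed_logit(tbl, n_quad=7)
        # oracle: pooled empirical logit per cell mapped through the coding
        merged = tbl.groupby(["group", "day"])[["n_correct", "n_incorrect"]].sum()
        for g in design.GROUPS:
            for d in design.DAYS:
                k, m = merged.loc[(g, d)]
                emp = math.log(k / m)
                assert fit.cell_logit(g, d) == pytest.approx(emp, abs=1e-3)
        assert fit.sigma_u < 0.05  # boundary behavior

    def test_matches_lme4_oracle(self, tmp_path):
        """Independent cross-check against glmer on the same data."""
        tbl = _simulate_counts(7)
        fit = stats.fit_mixed_logit(tbl)
        csv = tmp_path / "counts.csv"
        tbl.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
d$group <- factor(d$group, levels=c("NTBT","NTBC","NCBT","NCBC"))
d$day <- factor(d$day, levels=c("pre","d1","d2","d3"))
m <- glmer(cbind(n_correct, n_incorrect) ~ group*day + (1|participant),
           data=d, family=binomial, nAGQ=11)
co <- summary(m)$coefficients
cat(jsonlite::toJSON(list(beta=unname(co[,1]), se=unname(co[,2]),
    sigma=sqrt(unname(unlist(VarCorr(m))))), digits=10))
""")
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, check=True)
        ref = json.loads(out.stdout)
        np.testing.assert_allclose(fit.beta, ref["beta"], atol=2e-3)
        assert fit.sigma_u == pytest.approx(ref["sigma"][0], abs=5e-3)
        np.testing.assert_allclose(fit.se, ref["se"], rtol=0.1)

    def test_missing_cells_rejected(self):
        tbl = _simulate_counts(1)
        with pytest.raises(ParameterError):
            stats.fit_mixed_logit(tbl[tbl.group != "NCBC"])


class TestOddsRatios:
    def test_reference_table_reproduces_printed_contrasts(self):
        fit = stats.MixedLogitFit.from_estimates(design.REFERENCE_BETA)
        cases = [
            ((("NTBT", "d1"), ("NTBC", "d1")), 2.142),
            ((("NTBT", "pre"), ("NTBT", "d1")), 0.352),
            ((("NTBC", "pre"), ("NTBC", "d1")), 0.755),
            ((("NTBT", "d3"), ("NCBC", "d3")), 2.393),
            ((("NCBT", "d2"), ("NCBC", "d2")), 1.418),
            ((("NCBC", "pre"), ("NCBC", "d2")), 0.724),
        ]
        for (a, b), expected in cases:
            assert round(stats.odds_ratio_from_fit(fit, a, b).odds_ratio, 3) \
                == expected

    def test_identity_and_reciprocity(self):
        fit = stats.MixedLogitFit.from_estimates(design.REFERENCE_BETA)
        same = stats.odds_ratio_from_fit(fit, ("NCBT", "d2"), ("NCBT", "d2"))
        assert same.odds_ratio == 1.0
        ab = stats.odds_ratio_from_fit(fit, ("NTBT", "d1"), ("NCBC", "d2"))
        ba = stats.odds_ratio_from_fit(fit, ("NCBC", "d2"), ("NTBT", "d1"))
        assert ab.odds_ratio * ba.odds_ratio == pytest.approx(1.0, abs=1e-12)

    def test_transitivity_in_log_space(self):
        rng = np.random.default_rng(2)
        fit = stats.MixedLogitFit.from_estimates(rng.normal(0, 1, design.N_COEF))
        cells = [(g, d) for g in design.GROUPS for d in design.DAYS]
        for a, b, c in itertools.islice(itertools.permutations(cells, 3), 30):
            ac = stats.odds_ratio_from_fit(fit, a, c).log_odds_diff
            ab = stats.odds_ratio_from_fit(fit, a, b).log_odds_diff
            bc = stats.odds_ratio_from_fit(fit, b, c).log_odds_diff
            assert ac == pytest.approx(ab + bc, abs=1e-12)

    def test_unknown_cell(self):
        fit = stats.MixedLogitFit.from_estimates(design.REFERENCE_BETA)
        with pytest.raises(ParameterError):
            stats.odds_ratio_from_fit(fit, ("XXXX", "d1"), ("NTBT", "d1"))


class TestWaldType3:
    def test_term_dfs_and_single_coefficient_consistency(self):
        fit = stats.fit_mixed_logit(_simulate_counts(3, n_per_group=4,
                                                     n_trials=48), n_quad=5)
        w = stats.wald_type3(fit)
        assert list(w["df"]) == [3, 3, 9]
        # a 1-coefficient Wald block equals z^2
        j = 4
        chi1 = fit.beta[j] ** 2 / fit.vcov[j, j]
        z2 = (fit.beta[j] / fit.se[j]) ** 2
        assert chi1 == pytest.approx(z2, rel=1e-10)

    def test_interaction_chi2_invariant_to_reference_relabeling(self):
        """Re-expressing the fit under a swapped reference group (an exact
        linear reparametrization of the same model) leaves the interaction
        chi-square unchanged; the dummy-coded main-effect blocks test
        reference-dependent simple effects and are expected to move."""
        fit = stats.fit_mixed_logit(_simulate_counts(4, n_per_group=4,
                                                     n_trials=48), n_quad=5)
        swap = {"NTBT": "NCBC", "NCBC": "NTBT", "NTBC": "NCBT", "NCBT": "NTBC"}
        cells = [(g, d) for g in design.GROUPS for d in design.DAYS]
        x1 = np.stack([design.design_row(g, d) for g, d in cells])
        x2 = np.stack([design.design_row(swap[g], d) for g, d in cells])
        A = np.linalg.solve(x2, x1)   # beta2 = A beta1 gives identical cells
        fit2 = stats.MixedLogitFit(A @ fit.beta, vcov=A @ fit.vcov @ A.T,
                                   sigma_u=fit.sigma_u)
        w1 = stats.wald_type3(fit).set_index("term")
        w2 = stats.wald_type3(fit2).set_index("term")
        assert w1.loc["Group:Day", "chi2"] == pytest.approx(
            w2.loc["Group:Day", "chi2"], rel=1e-8)
        # groups-equal-at-pre is the same hypothesis under any group
        # permutation, so the Group block is invariant too ...
        assert w1.loc["Group", "chi2"] == pytest.approx(
            w2.loc["Group", "chi2"], rel=1e-8)
        # ... while the Day block tests days within the reference group,
        # which the swap changes
        assert w1.loc["Day", "chi2"] != pytest.approx(
            w2.loc["Day", "chi2"], rel=1e-3)

    def test_null_type_one_error_calibrated(self):
        """Monte-Carlo: with all group/day effects zero each Wald test
        rejects at ~5% (scaled-down cohort, 500 replicates)."""
        rej = {"Group": 0, "Day": 0, "Group:Day": 0}
        n_rep = 500
        rng = np.random.default_rng(0)
        for _ in range(n_rep):
            prof = synth.make_profiles(rng, n_per_group=4)
            tbl = synth.simulate_bad_counts(synth.SimCoefficients.null(),
                                            prof, n_trials=48, seed=rng)
            w = stats.wald_type3(stats.fit_mixed_logit(tbl, n_quad=5))
            for _, r in w.iterrows():
                if r["p"] < 0.05:
                    rej[r["term"]] += 1
        for term, count in rej.items():
            assert 0.03 <= count / n_rep <= 0.07, (term, count / n_rep)


class TestPairwiseAdjustment:
    def _contrasts(self, zs):
        return [stats.ContrastResult(f"c{i}", z, se=1.0, z=z,
                                     p=2 * spstats.norm.sf(abs(z)))
                for i, z in enumerate(zs)]

    def test_single_contrast_unadjusted(self):
        out = stats.adjust_pairwise(self._contrasts([2.1]), "tukey", n_means=4)
        assert out[0].p_adjusted == pytest.approx(out[0].p)

    def test_adjusted_at_least_unadjusted_and_monotone(self):
        zs = [0.5, 1.2, 1.9, 2.6, 3.3, 4.0]
        out = stats.adjust_pairwise(self._contrasts(zs), "tukey", n_means=4)
        for r in out:
            assert r.p_adjusted >= r.p - 1e-12
        padj = [r.p_adjusted for r in out]
        assert padj == sorted(padj, reverse=True)

    def test_tukey_matches_studentized_range(self):
        out = stats.adjust_pairwise(self._contrasts([2.5]) * 6, "tukey",
                                    n_means=4)
        expected = spstats.studentized_range.sf(2.5 * math.sqrt(2), 4, 1e7)
        assert out[0].p_adjusted == pytest.approx(float(expected), rel=1e-6)

    def test_familywise_error_near_nominal(self):
        """Null MC for 4 means (6 pairwise z contrasts): the chance of any
        Tukey-adjusted p < .05 should be ~5%."""
        rng = np.random.default_rng(8)
        crit = float(spstats.studentized_range.ppf(0.95, 4, 1e7))
        means = rng.standard_normal((20000, 4))
        ranges = means.max(axis=1) - means.min(axis=1)
        # range/1 == max |z_ij| * sqrt(2) for unit-variance means
        fwe = float(np.mean(ranges > crit))
        assert fwe == pytest.approx(0.05, abs=0.01)


def _anova_data(seed, n=8, genuine_slope=0.0, noise=0.08):
    rng = np.random.default_rng(seed)
    rows = []
    for nf in ("genuine", "sham"):
        for bt in ("feedback", "none"):
            for s in range(n):
                pid = f"{nf[:1]}{bt[:1]}{s}"
                base = rng.normal(0.5, 0.05)
                for di, day in enumerate(("d1", "d2", "d3")):
                    eff = genuine_slope * di if nf == "genuine" else 0.0
                    rows.append(dict(participant=pid, nf=nf, bt=bt, day=day,
                                     value=base + eff + rng.normal(0, noise)))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        df = _anova_data(0, noise=0.0, genuine_slope=0.0)
        df["value"] = 0.4
        res = stats.mixed_anova(df)
        assert (res.table["F"] == 0.0).all()

    def test_unbalanced_rejected(self):
        df = _anova_data(1)
        with pytest.raises(ParameterError):
            stats.mixed_anova(df[df.participant != "gf0"])

    def test_matches_r_aov_oracle(self, tmp_path):
        df = _anova_data(2, genuine_slope=0.04)
        res = stats.mixed_anova(df)
        csv = tmp_path / "anova.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "aov.R"
        rscript.write_text(f"""
d <- read.csv("{csv}")
for (col in c("participant","nf","bt","day")) d[[col]] <- factor(d[[col]])
m <- aov(value ~ nf*bt*day + Error(participant/day), data=d)
s <- summary(m)
w <- s[["Error: participant:day"]][[1]]
b <- s[["Error: participant"]][[1]]
cat(jsonlite::toJSON(list(
  f_within=unname(w[["F value"]][1:4]),
  df_err_within=unname(w[["Df"]][5]),
  mse=unname(w[["Mean Sq"]][5]),
  f_between=unname(b[["F value"]][1:3])), digits=10))
""")
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, check=True)
        ref = json.loads(out.stdout)
        tab = res.table.set_index("effect")
        np.testing.assert_allclose(
            [tab.loc[e, "F"] for e in ("Day", "Day:NF", "Day:BT", "Day:NF:BT")],
            ref["f_within"], rtol=1e-8)
        np.testing.assert_allclose(
            [tab.loc[e, "F"] for e in ("NF", "BT", "NF:BT")],
            ref["f_between"], rtol=1e-8)
        assert res.df_within_error == ref["df_err_within"][0]
        assert res.mse_within == pytest.approx(ref["mse"][0])

    def test_simple_main_effect_detects_genuine_only_growth(self):
        df = _anova_data(3, genuine_slope=0.06, noise=0.06)
        res = stats.mixed_anova(df)
        sme = res.simple_main_effects.set_index("effect")
        assert sme.loc["Day within NF=genuine", "p"] < 0.01
        assert sme.loc["Day within NF=sham", "p"] > 0.05
        lsd = res.lsd
        row = lsd[(lsd.nf == "genuine") & (lsd.contrast == "d3 - d1")].iloc[0]
        assert row.significant and row["diff"] > 0
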