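"""Cohort statistics.

The behavioral analysis is a binomial mixed model

    cbind(n_correct, n_incorrect) ~ Group * Day + (1 | participant)

with logit link, dummy coding (reference cell NTBT/pre) and a single
Gaussian random intercept per participant.  The marginal likelihood is
maximized with adaptive Gauss-Hermite quadrature (Laplace approximation at
one node); fixed-effect covariance comes from the numerical Hessian at the
optimum.  Type III Wald chi-square tests assess the Group (df 3), Day
(df 3) and Group:Day (df 9) terms.  Pairwise cell contrasts are reported
as odds ratios with asymptotic z statistics and Tukey (studentized-range)
family adjustment.

The neural analysis is a mixed-design ANOVA on normalized MMN amplitudes
with two between-subject factors (neurofeedback genuine/sham, behavioral
training feedback/none) and one within-subject factor (training day),
including simple main effects of day within each neurofeedback level and
LSD day comparisons on the pooled within error.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats as spstats
from scipy.special import expit, gammaln, logsumexp

from . import design
from .errors import FitError, ParameterError

TERM_BLOCKS = {
    "Group": list(range(1, 4)),
    "Day": list(range(4, 7)),
    "Group:Day": list(range(7, 16)),
}


@dataclass
class MixedLogitFit:
    """Fitted (or externally supplied) Group x Day binomial mixed model."""

    beta: np.ndarray
    se: np.ndarray | None = None
    vcov: np.ndarray | None = None
    sigma_u: float | None = None
    loglik: float | None = None
    converged: bool = True
    names: tuple = design.COEF_NAMES

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (design.N_COEF,):
            raise ParameterError(f"beta must have length {design.N_COEF}")
        if self.vcov is not None:
            self.vcov = np.asarray(self.vcov, dtype=float)
            if self.vcov.shape != (design.N_COEF, design.N_COEF):
                raise ParameterError("vcov must be 16 x 16")
            if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
                raise ParameterError("vcov must be symmetric")
            if self.se is None:
                self.se = np.sqrt(np.diag(self.vcov))

    @classmethod
    def from_estimates(
        cls, beta, sigma_u: float | None = None, loglik: float | None = None
    ) -> "MixedLogitFit":
        """Wrap a printed coefficient table (no covariance available)."""
        return cls(np.asarray(beta, dtype=float), sigma_u=sigma_u, loglik=loglik)

    def cell_logit(self, group: str, day: str) -> float:
        return design.cell_logit(self.beta, group, day)


@dataclass
class ContrastResult:
    """Log-odds difference between two design cells."""

    label: str
    log_odds_diff: float
    se: float | None = None
    z: float | None = None
    p: float | None = None
    p_adjusted: float | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_odds_diff)


def _prepare(table: pd.DataFrame):
    need = {"participant", "group", "day", "n_correct", "n_incorrect"}
    if not need.issubset(table.columns):
        raise ParameterError(f"table must have columns {sorted(need)}")
    for g in design.GROUPS:
        if not (table["group"] == g).any():
            raise ParameterError(f"group {g} missing from the table")
    for d in design.DAYS:
        if not (table["day"] == d).any():
            raise ParameterError(f"day {d} missing from the table")
    pids = list(dict.fromkeys(table["participant"]))
    rows_x, rows_k, rows_n = [], [], []
    for pid in pids:
        sub = table[table["participant"] == pid]
        rows_x.append(np.stack([design.design_row(g, d)
                                for g, d in zip(sub["group"], sub["day"])]))
        rows_k.append(sub["n_correct"].to_numpy(dtype=float))
        rows_n.append((sub["n_correct"] + sub["n_incorrect"]).to_numpy(dtype=float))
    n_obs = {x.shape[0] for x in rows_x}
    if len(n_obs) != 1:
        raise ParameterError("all participants need the same number of cells")
    X = np.stack(rows_x)          # (P, J, 16)
    K = np.stack(rows_k)          # (P, J)
    N = np.stack(rows_n)
    const = float(np.sum(gammaln(N + 1) - gammaln(K + 1) - gammaln(N - K + 1)))
    return X, K, N, const, pids


def _binll_terms(eta, K, N):
    # sum_j k*eta - n*log(1+e^eta), numerically safe log1p(exp)
    return np.sum(K * eta - N * np.logaddexp(0.0, eta), axis=-1)


def _participant_loglik(eta0, K, N, sigma, nodes, weights):
    """Adaptive GH marginal log-likelihood per participant (vectorized).

    eta0: (P, J) linear predictors without the random intercept.
    """
    if sigma < 1e-8:
        return _binll_terms(eta0, K, N)
    # inner Newton for the posterior mode of u
    u = np.zeros(eta0.shape[0])
    for _ in range(30):
        eta = eta0 + u[:, None]
        p = expit(eta)
        g = np.sum(K - N * p, axis=1) - u / sigma**2
        h = -np.sum(N * p * (1.0 - p), axis=1) - 1.0 / sigma**2
        step = g / h
        u = u - step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + u[:, None]
    p = expit(eta)
    h = -np.sum(N * p * (1.0 - p), axis=1) - 1.0 / sigma**2
    tau = 1.0 / np.sqrt(-h)
    # integral e^{f(u)} du, f = binll - u^2/(2 sigma^2) - log(sigma sqrt(2 pi))
    uq = u[:, None] + math.sqrt(2.0) * tau[:, None] * nodes[None, :]   # (P, Q)
    fq = _binll_terms(eta0[:, None, :] + uq[:, :, None], K[:, None, :], N[:, None, :])
    fq = fq - uq**2 / (2.0 * sigma**2) - math.log(sigma * math.sqrt(2.0 * math.pi))
    logint = logsumexp(fq + nodes[None, :] ** 2 + np.log(weights)[None, :], axis=1)
    return logint + np.log(math.sqrt(2.0) * tau)


def fit_mixed_logit(
    table: pd.DataFrame,
    n_quad: int = 11,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> MixedLogitFit:
    """Maximum-likelihood fit of the Group x Day binomial mixed model.

    ``table`` holds one row per participant x day with correct/incorrect
    counts.  ``n_quad`` adaptive Gauss-Hermite nodes (1 = Laplace).
    Raises :class:`FitError` on non-convergence or a singular covariance;
    warns on apparent separation (|beta| > 10).
    """
    X, K, N, const, _ = _prepare(table)
    nodes, weights = hermgauss(max(1, n_quad))

    def nll(params):
        beta, sigma = params[:-1], params[-1]
        eta0 = X @ beta
        return -(np.sum(_participant_loglik(eta0, K, N, sigma, nodes, weights)) + const)

    # starting values: plain binomial GLM (ignoring the random intercept)
    import statsmodels.api as sm

    Xf = X.reshape(-1, design.N_COEF)
    glm = sm.GLM(np.column_stack([K.ravel(), (N - K).ravel()]), Xf,
                 family=sm.families.Binomial()).fit()
    x0 = np.concatenate([glm.params, [0.3]])
    bounds = [(None, None)] * design.N_COEF + [(1e-8, 10.0)]
    res = optimize.minimize(
        nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": max(tol, 1e-8)},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        raise FitError(f"mixed logit did not converge: {res.message}")
    beta = res.x[:-1]
    sigma = float(res.x[-1])
    if np.any(np.abs(beta) > 10):
        warnings.warn("possible separation: |beta| > 10", stacklevel=2)

    from statsmodels.tools.numdiff import approx_hess1, approx_hess3

    def try_invert(hess, keep_beta_block):
        try:
            v = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return None
        if np.any(np.diag(v) <= 0):
            return None
        return v[: design.N_COEF, : design.N_COEF] if keep_beta_block else v

    # full Hessian (fixed-effect SEs then reflect sigma uncertainty) with a
    # forward-difference first pass; central differences as fallback, and a
    # beta-only block when sigma sits on its boundary.
    vcov = None
    if sigma > 1e-4:
        vcov = try_invert(approx_hess1(res.x, nll), True)
        if vcov is None:
            vcov = try_invert(approx_hess3(res.x, nll), True)
    if vcov is None:
        bnll = lambda b: nll(np.concatenate([b, [sigma]]))  # noqa: E731
        vcov = try_invert(approx_hess1(beta, bnll), False)
        if vcov is None:
            vcov = try_invert(approx_hess3(beta, bnll), False)
    if vcov is None:
        raise FitError("could not obtain a positive-definite covariance")
    vcov = (vcov + vcov.T) / 2.0
    return MixedLogitFit(
        beta=beta, vcov=vcov, sigma_u=sigma, loglik=-float(res.fun),
        converged=bool(res.success),
    )


def odds_ratio_from_fit(
    fit: MixedLogitFit, cell_a: tuple[str, str], cell_b: tuple[str, str]
) -> ContrastResult:
    """Odds ratio of cell A versus cell B from the fixed effects.

    log OR = (x_A - x_B) . beta; the delta-method SE uses the fixed-effect
    covariance when available (printed coefficient tables have none).
    """
    xa = design.design_row(*cell_a)
    xb = design.design_row(*cell_b)
    d = xa - xb
    diff = float(d @ fit.beta)
    label = f"{cell_a[0]}/{cell_a[1]} - {cell_b[0]}/{cell_b[1]}"
    if fit.vcov is None:
        return ContrastResult(label, diff)
    se = float(np.sqrt(d @ fit.vcov @ d))
    if se == 0.0:
        return ContrastResult(label, diff, se=0.0)
    z = diff / se
    p = 2.0 * spstats.norm.sf(abs(z))
    return ContrastResult(label, diff, se=se, z=z, p=p)


def wald_type3(fit: MixedLogitFit) -> pd.DataFrame:
    """Type III Wald chi-square tests of the Group, Day and interaction
    terms (df 3, 3, 9 under the dummy-coded model)."""
    if fit.vcov is None:
        raise FitError("Wald tests require the fitted covariance")
    rows = []
    for term, idx in TERM_BLOCKS.items():
        b = fit.beta[idx]
        v = fit.vcov[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError as e:
            raise FitError(f"singular covariance block for term {term}") from e
        df = len(idx)
        rows.append({"term": term, "chi2": chi2, "df": df,
                     "p": float(spstats.chi2.sf(chi2, df))})
    return pd.DataFrame(rows)


def adjust_pairwise(
    results: Sequence[ContrastResult],
    method: str = "tukey",
    n_means: int | None = None,
) -> list[ContrastResult]:
    """Family-wise adjusted p-values for a family of pairwise contrasts.

    ``tukey`` uses the studentized range with ``n_means`` means (inferred
    from the family size m = k(k-1)/2 when omitted) at infinite df, the
    asymptotic analogue of Tukey's HSD; ``sidak``/``bonferroni``/``none``
    are available for non-mean families.  Adjustment is monotone in |z|
    and a single-contrast family is left unadjusted.
    """
    results = list(results)
    m = len(results)
    if any(r.z is None for r in results):
        raise ParameterError("contrasts need z statistics before adjustment")
    if n_means is None:
        k = (1 + math.sqrt(1 + 8 * m)) / 2
        n_means = int(round(k))
    out = []
    for r in results:
        if m == 1 or method == "none":
            padj = r.p
        elif method == "tukey":
            padj = float(spstats.studentized_range.sf(
                abs(r.z) * math.sqrt(2.0), n_means, 1e7))
        elif method == "sidak":
            padj = float(1.0 - (1.0 - r.p) ** m)
        elif method == "bonferroni":
            padj = float(min(1.0, r.p * m))
        else:
            raise ParameterError(f"unknown adjustment {method!r}")
        out.append(ContrastResult(r.label, r.log_odds_diff, r.se, r.z, r.p,
                                  min(1.0, padj)))
    return out


def pairwise_groups_on_day(
    fit: MixedLogitFit, day: str, method: str = "tukey"
) -> list[ContrastResult]:
    """The six group contrasts on one day (Tukey family of 4 means)."""
    pairs = list(itertools.combinations(design.GROUPS, 2))
    res = [odds_ratio_from_fit(fit, (a, day), (b, day)) for a, b in pairs]
    if fit.vcov is None:
        return res
    return adjust_pairwise(res, method, n_means=len(design.GROUPS))


def pairwise_days_in_group(
    fit: MixedLogitFit, group: str, method: str = "tukey"
) -> list[ContrastResult]:
    """The six day contrasts within one group (Tukey family of 4 means)."""
    pairs = list(itertools.combinations(design.DAYS, 2))
    res = [odds_ratio_from_fit(fit, (group, a), (group, b)) for a, b in pairs]
    if fit.vcov is None:
        return res
    return adjust_pairwise(res, method, n_means=len(design.DAYS))


# ---------------------------------------------------------------------------
# mixed-design ANOVA on normalized MMN


@dataclass
class AnovaResult:
    """Split-plot ANOVA tables for the 2 (NF) x 2 (BT) x 3 (day) design."""

    table: pd.DataFrame
    mse_within: float
    df_within_error: int
    simple_main_effects: pd.DataFrame
    lsd: pd.DataFrame


def mixed_anova(mmn_table: pd.DataFrame) -> AnovaResult:
    """Univariate mixed-design ANOVA on normalized MMN amplitudes.

    ``mmn_table`` is long format with columns participant, nf
    (genuine/sham), bt (feedback/none), day and value; the design must be
    complete and balanced (equal participants per between-subject cell,
    every participant measured on every day).  Between-subject effects are
    tested against subjects-within-groups; within-subject effects against
    the day x subject pooled error, whose mean square is the MSe used by
    the simple main effects of day (within each NF level) and the LSD day
    comparisons.
    """
    need = {"participant", "nf", "bt", "day", "value"}
    if not need.issubset(mmn_table.columns):
        raise ParameterError(f"mmn_table must have columns {sorted(need)}")
    nf_levels = sorted(mmn_table["nf"].unique())
    bt_levels = sorted(mmn_table["bt"].unique())
    day_levels = sorted(mmn_table["day"].unique())
    a, b, c = len(nf_levels), len(bt_levels), len(day_levels)
    if a != 2 or b != 2 or c < 2:
        raise ParameterError("design must be 2 (NF) x 2 (BT) x days")

    wide = mmn_table.pivot_table(index=["nf", "bt", "participant"],
                                 columns="day", values="value", aggfunc="first")
    if wide.isna().any().any():
        raise ParameterError("every participant needs a value for every day")
    counts = wide.groupby(level=["nf", "bt"]).size()
    if counts.nunique() != 1 or len(counts) != a * b:
        raise ParameterError("unbalanced design: equal participants per "
                             "between-subject cell required")
    n = int(counts.iloc[0])

    # data cube (a, b, n, c)
    Y = np.stack([
        np.stack([
            wide.loc[(nf, bt)].reindex(columns=day_levels).to_numpy()
            for bt in bt_levels
        ])
        for nf in nf_levels
    ])
    m = Y.mean()
    m_a = Y.mean(axis=(1, 2, 3))
    m_b = Y.mean(axis=(0, 2, 3))
    m_ab = Y.mean(axis=(2, 3))
    m_c = Y.mean(axis=(0, 1, 2))
    m_ac = Y.mean(axis=(1, 2))
    m_bc = Y.mean(axis=(0, 2))
    m_abc = Y.mean(axis=2)
    m_subj = Y.mean(axis=3)

    ss_a = b * c * n * np.sum((m_a - m) ** 2)
    ss_b = a * c * n * np.sum((m_b - m) ** 2)
    ss_ab = c * n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_subj = c * np.sum((m_subj - m_ab[:, :, None]) ** 2)
    ss_c = a * b * n * np.sum((m_c - m) ** 2)
    ss_ac = b * n * np.sum((m_ac - m_a[:, None] - m_c[None, :] + m) ** 2)
    ss_bc = a * n * np.sum((m_bc - m_b[:, None] - m_c[None, :] + m) ** 2)
    ss_abc = n * np.sum((
        m_abc - m_ac[:, None, :] - m_bc[None, :, :] - m_ab[:, :, None]
        + m_a[:, None, None] + m_b[None, :, None] + m_c[None, None, :] - m
    ) ** 2)
    ss_total = np.sum((Y - m) ** 2)
    ss_werr = max(0.0, ss_total - (ss_a + ss_b + ss_ab + ss_subj + ss_c
                                   + ss_ac + ss_bc + ss_abc))

    df_subj = a * b * (n - 1)
    df_werr = (c - 1) * a * b * (n - 1)
    ms_subj = ss_subj / df_subj
    ms_werr = ss_werr / df_werr

    def row(effect, ss, df1, ms_err, df2):
        ms = ss / df1
        if ms_err > 0:
            f = ms / ms_err
        else:
            # degenerate zero-error input: only a genuinely nonzero effect
            # (not float dust from the SS decomposition) is infinite
            f = math.inf if ms > 1e-10 else 0.0
        return {"effect": effect, "ss": ss, "df1": df1, "df2": df2,
                "F": f, "p": float(spstats.f.sf(f, df1, df2)) if f > 0 else 1.0}

    table = pd.DataFrame([
        row("NF", ss_a, a - 1, ms_subj, df_subj),
        row("BT", ss_b, b - 1, ms_subj, df_subj),
        row("NF:BT", ss_ab, (a - 1) * (b - 1), ms_subj, df_subj),
        row("Day", ss_c, c - 1, ms_werr, df_werr),
        row("Day:NF", ss_ac, (a - 1) * (c - 1), ms_werr, df_werr),
        row("Day:BT", ss_bc, (b - 1) * (c - 1), ms_werr, df_werr),
        row("Day:NF:BT", ss_abc, (a - 1) * (b - 1) * (c - 1), ms_werr, df_werr),
    ])

    sme_rows, lsd_rows = [], []
    n_level = b * n  # participants per NF level
    t_crit = spstats.t.ppf(0.975, df_werr)
    for ai, nf in enumerate(nf_levels):
        ss = n_level * np.sum((m_ac[ai] - m_a[ai]) ** 2)
        sme_rows.append(row(f"Day within NF={nf}", ss, c - 1, ms_werr, df_werr))
        se = math.sqrt(max(0.0, 2.0 * ms_werr / n_level))
        for i, j in itertools.combinations(range(c), 2):
            diff = float(m_ac[ai, j] - m_ac[ai, i])
            t = diff / se if se > 0 else 0.0
            lsd_rows.append({
                "nf": nf, "contrast": f"{day_levels[j]} - {day_levels[i]}",
                "diff": diff, "se": se, "t": t,
                "p": float(2 * spstats.t.sf(abs(t), df_werr)),
                "significant": abs(t) > t_crit,
            })
    return AnovaResult(
        table=table,
        mse_within=float(ms_werr),
        df_within_error=int(df_werr),
        simple_main_effects=pd.DataFrame(sme_rows),
        lsd=pd.DataFrame(lsd_rows),
    )
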