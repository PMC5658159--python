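"""Single-endpoint and repeated-measures comparators for the ordinal mRS.

The battery of analyses traditionally applied to the modified Rankin Scale
in stroke trials, each returning a uniform :class:`ComparatorResult`:

- fixed dichotomy (mRS <= 1) via logistic regression,
- raw-scale and utility-weighted linear regression,
- Cochran-Mantel-Haenszel shift (row-mean-scores-differ) test,
- proportional odds model (POM) and its restricted partial-proportional-odds
  extension (PPOM with a linear trend in the cut-specific log odds),
- adjacent-categories logit (ACAT) with category-specific effects,
- sliding dichotomy (success definition varies with baseline NIHSS band),
- repeated-measures GEE on the dichotomized outcome.

Standard model fits go through statsmodels; the restricted PPOM and the
stratified mean-score CMH statistic are implemented here because no
installed package exposes them directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.numdiff import approx_hess1

from .panel import TrialPanel

logger = logging.getLogger("strokemsm")

_Z95 = stats.norm.ppf(0.975)

DEFAULT_90D_WINDOW = (80.0, 100.0)


@dataclass
class ComparatorResult:
    """Uniform container for one analysis: statistics, CIs and a p-value."""

    method: str
    outcome: str
    statistics: list[tuple[str, float, float, float]]   # label, est, lo, hi
    p_value: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        for label, est, lo, hi in self.statistics:
            if np.isfinite([est, lo, hi]).all() and not lo <= est <= hi:
                raise ValueError(f"CI does not bracket estimate for {label}")

    def to_rows(self) -> list[dict]:
        rows = []
        if self.statistics:
            for label, est, lo, hi in self.statistics:
                rows.append({"method": self.method, "outcome": self.outcome,
                             "stat_name": label, "estimate": est,
                             "ci_lo": lo, "ci_hi": hi, "p": self.p_value})
        else:
            rows.append({"method": self.method, "outcome": self.outcome,
                         "stat_name": "", "estimate": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan,
                         "p": self.p_value})
        return rows


@dataclass(frozen=True)
class UtilityWeights:
    """Utility per mRS state, non-increasing with death at the minimum.

    Published patient-centred weights exist in the literature; they are
    supplied through configuration.  :meth:`placeholder` is a synthetic
    linear ramp used in tests, not the published values.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = self.values
        if len(v) != 7:
            raise ValueError("need one utility per state 0-6")
        if any(b > a for a, b in zip(v, v[1:])):
            raise ValueError("utilities must be non-increasing in state")
        if v[6] != min(v):
            raise ValueError("death must carry the minimum utility")

    @classmethod
    def placeholder(cls) -> "UtilityWeights":
        """Synthetic linear ramp (1, 5/6, ..., 1/6, 0) — stands in for the
        published weights in tests and examples."""
        return cls(tuple((6 - s) / 6 for s in range(7)))

    def apply(self, states: Sequence[int]) -> np.ndarray:
        return np.asarray([self.values[int(s)] for s in states], float)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def dichotomize(states: Sequence[int], cut: int = 1) -> np.ndarray:
    """Favorable-outcome indicator: 1 iff state <= cut (default mRS <= 1)."""
    arr = np.asarray(states, int)
    if ((arr < 0) | (arr > 6)).any():
        raise ValueError("states must lie in 0-6")
    return (arr <= cut).astype(int)


def visit_outcomes(panel: TrialPanel,
                   window: tuple[float, float] = DEFAULT_90D_WINDOW,
                   carry_death: bool = True,
                   adjust: Sequence[str] = ()) -> pd.DataFrame:
    """One outcome row per subject at the visit in `window`.

    With `carry_death` (the single-endpoint convention) a subject who died
    before the window is included with state 6 at the window midpoint even
    though the death record itself lies outside the window.  Requested
    baseline covariates are merged in; subjects missing them are dropped
    with a log entry.
    """
    sel = panel.at_visit(window).copy()
    if carry_death:
        death_states = panel.state_space.absorbing
        last = panel.data.groupby("subject_id", sort=False).tail(1)
        dead = last[last["state"].isin(death_states)
                    & (last["time_days"] <= window[1])]
        dead = dead[~dead["subject_id"].isin(sel["subject_id"])]
        if len(dead):
            carried = dead.copy()
            carried["time_days"] = 0.5 * (window[0] + window[1])
            sel = pd.concat([sel, carried], ignore_index=True)
    sel = sel.sort_values("subject_id", kind="stable").reset_index(drop=True)
    sel["treat"] = (sel["arm"] == "treatment").astype(int)
    adjust = list(adjust)
    if adjust:
        if panel.baseline is None:
            raise ValueError("panel has no baseline covariates to adjust for")
        missing_cols = set(adjust) - set(panel.baseline.columns)
        if missing_cols:
            raise ValueError(f"unknown adjusters: {sorted(missing_cols)}")
        sel = sel.merge(panel.baseline[adjust].reset_index(),
                        on="subject_id", how="left")
        incomplete = sel[adjust].isna().any(axis=1)
        if incomplete.any():
            logger.warning("excluding %d subject(s) with missing adjusters",
                           int(incomplete.sum()))
            sel = sel[~incomplete]
    return sel


def _wald_or(coef: float, se: float, p: float, label: str = "OR"
             ) -> tuple[str, float, float, float]:
    return (label, float(np.exp(coef)), float(np.exp(coef - _Z95 * se)),
            float(np.exp(coef + _Z95 * se)))


# ---------------------------------------------------------------------------
# Single-endpoint analyses
# ---------------------------------------------------------------------------

def logistic_endpoint(panel: TrialPanel,
                      window: tuple[float, float] = DEFAULT_90D_WINDOW,
                      adjust: Sequence[str] = (), cut: int = 1,
                      ) -> ComparatorResult:
    """Logistic regression of the fixed dichotomy (mRS <= cut) on arm."""
    df = visit_outcomes(panel, window, adjust=adjust)
    y = dichotomize(df["state"], cut=cut)
    X = sm.add_constant(df[["treat"] + list(adjust)].astype(float))
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception as exc:          # separation or non-convergence
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    b, se = fit.params["treat"], fit.bse["treat"]
    p = float(fit.pvalues["treat"])
    return ComparatorResult(
        method="logistic", outcome=f"mRS at 90 d (0-{cut} vs. {cut + 1}-6)",
        statistics=[_wald_or(b, se, p)], p_value=p,
        extra={"llf": float(fit.llf), "n": int(fit.nobs)})


def linear_endpoint(panel: TrialPanel,
                    window: tuple[float, float] = DEFAULT_90D_WINDOW,
                    transform: str = "identity",
                    adjust: Sequence[str] = (),
                    weights: UtilityWeights | None = None,
                    ) -> ComparatorResult:
    """Linear model of the raw or utility-weighted mRS on arm.

    Direction convention (labelled in the output): for the raw scale the
    reported difference is control minus treatment (positive = benefit);
    for utilities it is treatment minus control (positive = benefit).
    """
    if transform not in ("identity", "utility"):
        raise ValueError("transform must be 'identity' or 'utility'")
    df = visit_outcomes(panel, window, adjust=adjust)
    if transform == "utility":
        if weights is None:
            raise ValueError("utility transform requires UtilityWeights")
        y = weights.apply(df["state"])
        sign, label = +1.0, "diff_means (treatment - control)"
        outcome = "UW-mRS at 90 d"
    else:
        y = df["state"].to_numpy(float)
        sign, label = -1.0, "diff_means (control - treatment)"
        outcome = "mRS at 90 d (continuous)"
    X = sm.add_constant(df[["treat"] + list(adjust)].astype(float))
    fit = sm.OLS(y, X).fit()
    b, se = fit.params["treat"], fit.bse["treat"]
    p = float(fit.pvalues["treat"])
    est = sign * b
    return ComparatorResult(
        method="linear" if transform == "identity" else "uw_linear",
        outcome=outcome,
        statistics=[(label, float(est), float(est - _Z95 * se),
                     float(est + _Z95 * se))],
        p_value=p, extra={"n": int(fit.nobs)})


def cmh_shift(tables: pd.DataFrame | np.ndarray | Sequence,
              scores: str = "integer") -> ComparatorResult:
    """Stratified CMH row-mean-scores-differ test on 2 x K count tables.

    `tables` is one 2 x K table (single stratum) or a sequence of them.
    ``scores="integer"`` uses 0..K-1 column scores; ``"ridit"`` uses
    modified ridit (midrank / (N + 1)) scores per stratum.  The statistic is
    chi-square with 1 df; there is no effect-size estimate.
    """
    if isinstance(tables, (pd.DataFrame, np.ndarray)):
        tables = [tables]
    tables = [np.asarray(t, float) for t in tables]
    if not tables or any(t.size == 0 for t in tables):
        raise ValueError("empty contingency table")
    num, var = 0.0, 0.0
    for t in tables:
        if t.shape[0] != 2:
            raise ValueError("each stratum must be a 2 x K table")
        N = t.sum()
        if N == 0:
            continue
        col = t.sum(axis=0)
        if scores == "integer":
            a = np.arange(t.shape[1], dtype=float)
        elif scores == "ridit":
            midrank = np.cumsum(col) - 0.5 * col + 0.5
            a = midrank / (N + 1.0)
        else:
            raise ValueError("scores must be 'integer' or 'ridit'")
        n1, n2 = t[0].sum(), t[1].sum()
        T = float(a @ t[0])
        E = n1 * float(a @ col) / N
        s1, s2 = float(a @ col), float(a * a @ col)
        if N > 1:
            var += n1 * n2 * (N * s2 - s1 ** 2) / (N ** 2 * (N - 1))
        num += T - E
    if var <= 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = num ** 2 / var
        p = float(stats.chi2.sf(statistic, 1))
    return ComparatorResult(
        method="shift", outcome="mRS at 90 d",
        statistics=[], p_value=p,
        extra={"chi2": float(statistic), "df": 1, "scores": scores})


def pom_fit(panel: TrialPanel,
            window: tuple[float, float] = DEFAULT_90D_WINDOW,
            adjust: Sequence[str] = ()) -> ComparatorResult:
    """Proportional odds (cumulative logit) model with one arm coefficient.

    The reported OR is oriented so that OR > 1 means better (lower) mRS
    with treatment, the shift-analysis convention.
    """
    df = visit_outcomes(panel, window, adjust=adjust)
    if df["state"].nunique() < 3:
        raise ValueError("need at least 3 outcome categories for a POM")
    y = pd.Categorical(df["state"], ordered=True)
    X = df[["treat"] + list(adjust)].astype(float)
    model = OrderedModel(y, X, distr="logit")
    fit = model.fit(method="bfgs", disp=0, maxiter=200)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("POM did not converge")
    b, se = fit.params["treat"], fit.bse["treat"]
    p = float(fit.pvalues["treat"])
    # OrderedModel: P(Y<=j) = F(theta_j - x beta); flip the sign so OR > 1
    # favors lower categories under treatment
    return ComparatorResult(
        method="pom", outcome="mRS at 90 d",
        statistics=[_wald_or(-b, se, p)], p_value=p,
        extra={"llf": float(fit.llf), "n": int(fit.nobs)})


# -- restricted PPOM (linear deviation from proportional odds) --------------

def _ppom_nll(theta: np.ndarray, k: np.ndarray, treat: np.ndarray,
              A: np.ndarray, n_cuts: int, n_adj: int,
              trend: bool) -> float:
    cuts = theta[:n_cuts]
    beta0 = theta[n_cuts]
    gamma = theta[n_cuts + 1] if trend else 0.0
    badj = theta[n_cuts + 1 + int(trend):]
    eta_adj = A @ badj if n_adj else 0.0
    j = np.arange(n_cuts)
    # logit P(Y <= cut_j) = cuts_j + treat * (beta0 + gamma j) - eta_adj
    lin = cuts[None, :] + np.outer(treat, beta0 + gamma * j)
    if n_adj:
        lin = lin - np.asarray(eta_adj)[:, None]
    C = 1.0 / (1.0 + np.exp(-lin))                      # (n, n_cuts)
    full = np.concatenate([np.zeros((len(k), 1)), C,
                           np.ones((len(k), 1))], axis=1)
    probs = full[np.arange(len(k)), k + 1] - full[np.arange(len(k)), k]
    if (probs <= 1e-12).any():
        return 1e10
    return -float(np.log(probs).sum())


def ppom_restricted_fit(panel: TrialPanel,
                        window: tuple[float, float] = DEFAULT_90D_WINDOW,
                        adjust: Sequence[str] = (),
                        linear_trend: bool = True) -> ComparatorResult:
    """Cumulative-logit model whose arm log-odds vary linearly across cuts.

    The arm effect at cut j is beta0 + gamma * j, so the fitted cut-specific
    log odds ratios form an exact arithmetic sequence; gamma = 0 recovers
    the proportional odds model.  Reports every cut-specific OR with a
    delta-method CI and the LRT p-value (2 df with the trend, 1 df without)
    against the no-arm-effect model.
    """
    df = visit_outcomes(panel, window, adjust=adjust)
    cats = np.sort(df["state"].unique())
    if len(cats) < 3:
        raise ValueError("need at least 3 outcome categories")
    k = np.searchsorted(cats, df["state"].to_numpy())
    treat = df["treat"].to_numpy(float)
    A = df[list(adjust)].to_numpy(float) if adjust else np.zeros((len(df), 0))
    n_cuts, n_adj = len(cats) - 1, len(adjust)

    cum = np.array([(k <= j).mean() for j in range(n_cuts)])
    cut0 = np.log(cum / (1 - cum))
    n_arm = 1 + int(linear_trend)

    def fit_at(free_arm: bool) -> tuple[np.ndarray, float]:
        x0 = np.concatenate([cut0, np.zeros(n_arm + n_adj)])

        def nll(th):
            full = th.copy()
            if not free_arm:
                full = np.concatenate([th[:n_cuts], np.zeros(n_arm),
                                       th[n_cuts:]])
            return _ppom_nll(full, k, treat, A, n_cuts, n_adj, linear_trend)

        start = x0 if free_arm else np.concatenate([cut0, np.zeros(n_adj)])
        res = optimize.minimize(nll, start, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-7})
        if not res.success and np.max(np.abs(res.jac)) > 1e-3:
            raise RuntimeError(f"PPOM fit failed: {res.message}")
        return res.x, -res.fun

    th1, llf1 = fit_at(True)
    _, llf0 = fit_at(False)
    statistic = max(2.0 * (llf1 - llf0), 0.0)
    p = float(stats.chi2.sf(statistic, n_arm))

    H = approx_hess1(th1, lambda t: _ppom_nll(t, k, treat, A, n_cuts,
                                              n_adj, linear_trend))
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.full((len(th1), len(th1)), np.nan)
    beta0 = th1[n_cuts]
    gamma = th1[n_cuts + 1] if linear_trend else 0.0
    statistics = []
    for j in range(n_cuts):
        log_or = beta0 + gamma * j
        if linear_trend:
            var = (V[n_cuts, n_cuts] + j * j * V[n_cuts + 1, n_cuts + 1]
                   + 2 * j * V[n_cuts, n_cuts + 1])
        else:
            var = V[n_cuts, n_cuts]
        se = np.sqrt(var) if var > 0 else np.nan
        lo_state = cats[j]
        label = (f"OR 0-{lo_state} vs. {cats[j + 1]}-6"
                 if lo_state else f"OR 0 vs. {cats[j + 1]}-6")
        statistics.append((label, float(np.exp(log_or)),
                           float(np.exp(log_or - _Z95 * se)),
                           float(np.exp(log_or + _Z95 * se))))
    return ComparatorResult(
        method="ppom", outcome="mRS at 90 d",
        statistics=statistics, p_value=p,
        extra={"llf": float(llf1), "beta0": float(beta0),
               "gamma": float(gamma), "df": n_arm, "n": len(df)})


def acat_fit(panel: TrialPanel,
             window: tuple[float, float] = DEFAULT_90D_WINDOW,
             adjust: Sequence[str] = ()) -> ComparatorResult:
    """Adjacent-categories logit with category-specific arm effects.

    Fitted as an unconstrained multinomial logit (the two models are
    reparametrizations of each other); reported ORs compare the odds of
    the lower versus the higher of each adjacent category pair under
    treatment, so OR > 1 favors the better outcome.  The p-value is the
    (K-1)-df LRT for any arm effect.
    """
    df = visit_outcomes(panel, window, adjust=adjust)
    cats = np.sort(df["state"].unique())
    K = len(cats)
    if K < 2:
        raise ValueError("need at least 2 outcome categories")
    k = np.searchsorted(cats, df["state"].to_numpy())
    X1 = sm.add_constant(df[["treat"] + list(adjust)].astype(float))
    X0 = sm.add_constant(df[list(adjust)].astype(float)) if adjust \
        else np.ones((len(df), 1))
    fit1 = sm.MNLogit(k, X1).fit(method="newton", disp=0, maxiter=200)
    fit0 = sm.MNLogit(k, X0).fit(method="newton", disp=0, maxiter=200)
    statistic = max(2.0 * (fit1.llf - fit0.llf), 0.0)
    p = float(stats.chi2.sf(statistic, K - 1))

    # params: (k_vars, K-1); cov_params ordered equation-major
    k_vars = X1.shape[1]
    pos_treat = list(X1.columns).index("treat")
    b = np.concatenate([[0.0], fit1.params.to_numpy()[pos_treat, :]])
    V = fit1.cov_params().to_numpy()

    def cov_treat(j1: int, j2: int) -> float:
        if j1 == 0 or j2 == 0:
            return 0.0
        i1 = (j1 - 1) * k_vars + pos_treat
        i2 = (j2 - 1) * k_vars + pos_treat
        return V[i1, i2]

    statistics = []
    for j in range(K - 1):
        log_or = b[j] - b[j + 1]          # favors the lower category
        var = cov_treat(j, j) + cov_treat(j + 1, j + 1) - 2 * cov_treat(j, j + 1)
        se = np.sqrt(var) if var > 0 else np.nan
        statistics.append((f"OR {cats[j]} vs. {cats[j + 1]}",
                           float(np.exp(log_or)),
                           float(np.exp(log_or - _Z95 * se)),
                           float(np.exp(log_or + _Z95 * se))))
    return ComparatorResult(
        method="acat", outcome="mRS at 90 d",
        statistics=statistics, p_value=p,
        extra={"llf": float(fit1.llf), "df": K - 1, "n": len(df)})


DEFAULT_SLIDING_BANDS = (7, 14)
"""NIHSS band edges: mild <= 7 (the published bands skip 7; it is folded
into the mild band for contiguity), moderate 8-14, severe > 14."""


def sliding_success(states: Sequence[int], nihss: Sequence[float],
                    bands: tuple[int, int] = DEFAULT_SLIDING_BANDS
                    ) -> np.ndarray:
    """Severity-dependent success: mRS 0 if NIHSS <= bands[0], mRS <= 1 if
    NIHSS <= bands[1], mRS <= 2 otherwise."""
    nihss = np.asarray(nihss, float)
    cut = np.where(nihss <= bands[0], 0, np.where(nihss <= bands[1], 1, 2))
    return (np.asarray(states, int) <= cut).astype(int)


def sliding_dichotomy(panel: TrialPanel,
                      window: tuple[float, float] = DEFAULT_90D_WINDOW,
                      bands: tuple[int, int] = DEFAULT_SLIDING_BANDS,
                      nihss_col: str = "nihss_total") -> ComparatorResult:
    """Responder analysis: success depends on baseline severity band.

    Success is mRS = 0 for mild stroke (NIHSS <= bands[0]), mRS <= 1 for
    moderate (bands[0] < NIHSS <= bands[1]) and mRS <= 2 for severe.  No
    NIHSS adjuster is entered — severity is already encoded in the outcome.
    """
    df = visit_outcomes(panel, window, adjust=(nihss_col,))
    y = sliding_success(df["state"], df[nihss_col], bands)
    X = sm.add_constant(df[["treat"]].astype(float))
    fit = sm.Logit(y, X).fit(disp=0)
    b, se = fit.params["treat"], fit.bse["treat"]
    p = float(fit.pvalues["treat"])
    return ComparatorResult(
        method="sliding", outcome=(
            f"mRS at 90 d (0 if NIHSS<={bands[0]}, 0-1 if "
            f"{bands[0] + 1}-{bands[1]}, 0-2 if >{bands[1]})"),
        statistics=[_wald_or(b, se, p)], p_value=p,
        extra={"n": int(fit.nobs)})


def gee_repeated(panel: TrialPanel,
                 visit_windows: Sequence[tuple[float, float]] | None = None,
                 with_baseline: bool = False,
                 cov_struct: str = "independence",
                 adjust: Sequence[str] = (), cut: int = 1,
                 ) -> ComparatorResult:
    """Marginal logistic GEE of the dichotomized outcome across visits.

    Deaths are carried forward as unfavorable at later visits.  With
    `with_baseline`, the attached time-0 latent baseline record joins the
    visit set (and no NIHSS adjuster should be used).  Robust sandwich
    standard errors throughout.
    """
    from .panel import DEFAULT_VISIT_WINDOWS
    windows = list(visit_windows or DEFAULT_VISIT_WINDOWS)
    if with_baseline:
        if not (panel.data["time_days"] == 0).any():
            raise ValueError("with_baseline requires attached time-0 records")
        windows = [(-0.5, 0.5)] + windows
    frames = []
    for w in windows:
        f = visit_outcomes(panel, w, adjust=adjust)
        f["visit_mid"] = 0.5 * (w[0] + w[1])
        frames.append(f)
    long = pd.concat(frames, ignore_index=True)
    per_subj = long.groupby("subject_id").size()
    if (per_subj <= 1).all():
        logger.warning("one visit per subject; falling back to a plain "
                       "logistic fit")
        return logistic_endpoint(panel, windows[0], adjust=adjust, cut=cut)
    long = long.sort_values(["subject_id", "visit_mid"], kind="stable")
    y = dichotomize(long["state"], cut=cut)
    X = sm.add_constant(long[["treat"] + list(adjust)].astype(float))
    cs = {"independence": sm.cov_struct.Independence,
          "exchangeable": sm.cov_struct.Exchangeable}[cov_struct]()
    fit = sm.GEE(y, X, groups=long["subject_id"],
                 family=sm.families.Binomial(), cov_struct=cs).fit()
    b, se = fit.params["treat"], fit.bse["treat"]
    p = float(fit.pvalues["treat"])
    label = "gee_baseline" if with_baseline else "gee"
    return ComparatorResult(
        method=label,
        outcome=("predicted mRS at baseline and " if with_baseline else "")
        + f"mRS over follow-up (0-{cut} vs. {cut + 1}-6)",
        statistics=[_wald_or(b, se, p)], p_value=p,
        extra={"n_obs": int(fit.nobs), "cov_struct": cov_struct})


# ---------------------------------------------------------------------------
# The battery
# ---------------------------------------------------------------------------

#: Analyses that accept a baseline-NIHSS adjuster; the shift test (no
#: continuous covariates), the sliding dichotomy and every with-baseline
#: analysis (severity already encoded) never adjust.
_ADJUSTABLE = {"logistic", "linear", "uw_linear", "pom", "ppom", "acat",
               "gee"}

DEFAULT_BATTERY = ("logistic", "linear", "shift", "pom", "ppom", "acat",
                   "sliding", "uw_linear", "gee", "gee_baseline",
                   "msmm", "msmm_baseline")


def run_battery(panel: TrialPanel, methods: Sequence[str] = DEFAULT_BATTERY,
                adjust: str = "none",
                window: tuple[float, float] = DEFAULT_90D_WINDOW,
                utility_weights: UtilityWeights | None = None,
                sliding_bands: tuple[int, int] = DEFAULT_SLIDING_BANDS,
                target_dist: Mapping[int, float] | None = None,
                msmm_options: Mapping | None = None,
                ) -> list[ComparatorResult]:
    """Run the configured battery of analyses, one ComparatorResult each.

    `adjust="nihss"` adds the baseline NIHSS total to every analysis that
    accommodates it.  A failing method is logged and reported with a NaN
    p-value; the remaining methods still run.
    """
    from .battery_msmm import msmm_comparator      # local: avoids cycle
    adjusters = ("nihss_total",) if adjust == "nihss" else ()
    weights = utility_weights or UtilityWeights.placeholder()
    msmm_options = dict(msmm_options or {})

    def shift_runner() -> ComparatorResult:
        df = visit_outcomes(panel, window)
        table = pd.crosstab(df["arm"], df["state"]).reindex(
            index=["control", "treatment"], fill_value=0)
        return cmh_shift(table)

    runners: dict[str, Callable[[], ComparatorResult]] = {
        "logistic": lambda: logistic_endpoint(panel, window, adjusters),
        "linear": lambda: linear_endpoint(panel, window, "identity",
                                          adjusters),
        "shift": shift_runner,
        "pom": lambda: pom_fit(panel, window, adjusters),
        "ppom": lambda: ppom_restricted_fit(panel, window, adjusters),
        "acat": lambda: acat_fit(panel, window, adjusters),
        "sliding": lambda: sliding_dichotomy(panel, window, sliding_bands),
        "uw_linear": lambda: linear_endpoint(panel, window, "utility", adjusters,
                                             weights=weights),
        "gee": lambda: gee_repeated(panel, adjust=adjusters),
        "gee_baseline": lambda: msmm_comparator(
            panel, which="gee_baseline", target_dist=target_dist),
        "msmm": lambda: msmm_comparator(panel, which="msmm",
                                        options=msmm_options),
        "msmm_baseline": lambda: msmm_comparator(
            panel, which="msmm_baseline", target_dist=target_dist,
            options=msmm_options),
    }
    unknown = [m for m in methods if m not in runners]
    if unknown:
        raise ValueError(f"unknown analysis name(s) {unknown}; valid: "
                         f"{sorted(runners)}")
    results = []
    for m in methods:
        try:
            results.append(runners[m]())
        except Exception as exc:
            logger.error("analysis %r failed: %s", m, exc)
            results.append(ComparatorResult(
                method=m, outcome="", statistics=[], p_value=np.nan,
                extra={"error": str(exc)}))
    return results


def results_to_frame(results: Sequence[ComparatorResult]) -> pd.DataFrame:
    """Flatten results into the fixed-column CSV contract."""
    rows = []
    for r in results:
        rows.extend(r.to_rows())
    return pd.DataFrame(rows, columns=["method", "outcome", "stat_name",
                                       "estimate", "ci_lo", "ci_hi", "p"])
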