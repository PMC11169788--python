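"""Cohort-level inference: tertiles, trends, mediation, mixed models.

This module reproduces the inference layer of a segmental CMR biomarker
study: tertile stratification of the exposure with linear trend tests,
pairwise Pearson correlation matrices, bidirectional stepwise-AIC
multivariable regression with forced covariates, a bootstrap mediation
decomposition of the exposure's effect into direct and mediated paths,
random-intercept linear mixed models for segmental data and the
base-to-apex gradient, Holm step-down multiplicity adjustment, a logistic
model for a binary imaging flag, and exact two-sample t-test power.

Ordinary fits are delegated to statsmodels (OLS, MixedLM REML, Logit,
multipletests); the mediation decomposition, its bootstrap, stepwise
search and the stratification logic are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import (
    DegenerateDesignError,
    InvalidParameterError,
    SeparationError,
)

__all__ = [
    "TertileStratification",
    "MediationResult",
    "LMMResult",
    "tertile_stratify",
    "linear_trend_test",
    "pearson_matrix",
    "stepwise_aic",
    "fit_mediation",
    "effect_shares",
    "rmsea",
    "fit_mediation_no_direct",
    "fit_lmm_random_intercept",
    "base_to_apex_analysis",
    "holm_adjust",
    "logistic_lge",
    "power_two_sample_t",
]

TERTILE_LABELS = ("lower", "middle", "upper")


# ---------------------------------------------------------------------------
# Tertiles and trend tests
# ---------------------------------------------------------------------------


@dataclass
class TertileStratification:
    """Sample tertile cuts and per-subject labels.

    Cuts are the 1/3 and 2/3 type-7 sample quantiles; intervals are
    left-open right-closed, so lower = (-inf, q1], middle = (q1, q2],
    upper = (q2, inf). Missing values stay unlabeled.
    """

    boundaries: tuple
    labels: pd.Series  # categorical with TERTILE_LABELS; NaN where value missing
    n_missing: int = 0

    def counts(self) -> dict:
        return {k: int((self.labels == k).sum()) for k in TERTILE_LABELS}


def tertile_stratify(values) -> TertileStratification:
    ser = pd.Series(np.asarray(values, dtype=float))
    valid = ser.dropna()
    if valid.size < 3:
        raise InvalidParameterError("need at least 3 non-missing values for tertiles")
    q1, q2 = np.quantile(valid.to_numpy(), [1 / 3, 2 / 3])  # type-7 default
    if q1 == q2:
        raise DegenerateDesignError(
            "degenerate ties: tertile boundaries coincide; stratification undefined"
        )
    labels = pd.Series(index=ser.index, dtype="object")
    labels[ser <= q1] = "lower"
    labels[(ser > q1) & (ser <= q2)] = "middle"
    labels[ser > q2] = "upper"
    labels = labels.astype(pd.CategoricalDtype(TERTILE_LABELS, ordered=True))
    return TertileStratification((float(q1), float(q2)), labels, int(ser.isna().sum()))


@dataclass
class TrendTestResult:
    slope: float
    se: float
    p_value: float
    n: int


def linear_trend_test(outcome, tertile_labels) -> TrendTestResult:
    """OLS of the outcome on the tertile score 1/2/3 with a t-test on the slope."""
    y = pd.Series(np.asarray(outcome, dtype=float)).reset_index(drop=True)
    labels = pd.Series(tertile_labels).reset_index(drop=True)
    score = labels.map({k: i + 1 for i, k in enumerate(TERTILE_LABELS)}).astype(float)
    mask = y.notna() & score.notna()
    y, score = y[mask], score[mask]
    if score.nunique() < 2:
        raise DegenerateDesignError("trend test needs at least two populated groups")
    if np.ptp(y.to_numpy()) == 0:
        # constant outcome: slope identically zero, nothing to test
        return TrendTestResult(0.0, 0.0, 1.0, int(mask.sum()))
    x = sm.add_constant(score.to_numpy())
    fit = sm.OLS(y.to_numpy(), x).fit()
    return TrendTestResult(
        float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), int(mask.sum())
    )


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def pearson_matrix(table: pd.DataFrame, variables) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with t-distributed p-values.

    Returns (r, p, n) frames; cells with fewer than 3 complete pairs are NaN.
    """
    variables = list(variables)
    r = pd.DataFrame(np.nan, index=variables, columns=variables)
    p = pd.DataFrame(np.nan, index=variables, columns=variables)
    n = pd.DataFrame(0, index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i:]:
            pair = table[[a, b]].dropna() if a != b else table[[a]].dropna()
            m = len(pair)
            n.loc[a, b] = n.loc[b, a] = m
            if m < 3:
                continue
            if a == b:
                r.loc[a, b], p.loc[a, b] = 1.0, 0.0
                continue
            rr, pp = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = float(rr)
            p.loc[a, b] = p.loc[b, a] = float(pp)
    return r, p, n


# ---------------------------------------------------------------------------
# Stepwise AIC
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    selected: list
    forced: list
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    trace: list  # (action, term, aic) tuples


def _ols_aic(df: pd.DataFrame, outcome: str, terms) -> sm.regression.linear_model.RegressionResultsWrapper:
    formula = f"{outcome} ~ " + (" + ".join(terms) if terms else "1")
    return smf.ols(formula, data=df).fit()


def stepwise_aic(df: pd.DataFrame, outcome: str, candidates, forced=()) -> StepwiseResult:
    """Bidirectional stepwise model search minimizing AIC.

    Forced terms are always kept. At each step the single add or drop that
    most lowers AIC is applied; the search stops when no move improves.
    """
    candidates, forced = list(candidates), list(forced)
    data = df[[outcome] + candidates + forced].dropna()
    if len(data) <= len(candidates) + 2:
        raise DegenerateDesignError("too few complete cases for stepwise selection")
    current: list = []
    fit = _ols_aic(data, outcome, forced + current)
    best_aic = fit.aic
    trace = [("start", "", best_aic)]
    improved = True
    while improved:
        improved = False
        moves = [("add", t) for t in candidates if t not in current]
        moves += [("drop", t) for t in current]
        best_move, best_move_aic = None, best_aic
        for action, term in moves:
            trial = current + [term] if action == "add" else [t for t in current if t != term]
            aic = _ols_aic(data, outcome, forced + trial).aic
            if aic < best_move_aic - 1e-10:
                best_move, best_move_aic = (action, term), aic
        if best_move is not None:
            action, term = best_move
            current = current + [term] if action == "add" else [t for t in current if t != term]
            best_aic = best_move_aic
            trace.append((action, term, best_aic))
            improved = True
    fit = _ols_aic(data, outcome, forced + current)
    return StepwiseResult(current, forced, fit.params, fit.bse, fit.pvalues, float(fit.aic), trace)


# ---------------------------------------------------------------------------
# Mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Linear mediation decomposition X -> M -> Y with a direct path.

    ``a`` is the exposure->mediator slope, ``b`` the mediator->outcome
    slope adjusted for the exposure, ``c_prime`` the direct path;
    indirect = a*b and total = c_prime + a*b hold exactly. Percentile
    bootstrap CIs and SEs come from case resampling. ``standardized``
    holds the same paths on z-scored variables; ``per_scale`` rescales the
    direct/indirect/total effects to a ``scale``-unit change of the
    exposure. The saturated model has zero degrees of freedom, hence
    RMSEA 0 by construction.
    """

    a: float
    b: float
    c_prime: float
    indirect: float
    total: float
    share_indirect: float
    share_direct: float
    ci: dict
    boot_se: dict
    standardized: dict
    per_scale: dict
    scale: float
    n: int
    n_boot: int
    df: int = 0
    rmsea: float = 0.0


def _mediation_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    one = np.ones_like(x)
    a = np.linalg.lstsq(np.column_stack([one, x]), m, rcond=None)[0][1]
    coef = np.linalg.lstsq(np.column_stack([one, x, m]), y, rcond=None)[0]
    return float(a), float(coef[2]), float(coef[1])


def effect_shares(direct: float, indirect: float) -> tuple[float, float]:
    """Fractions of the total effect carried by the direct and indirect paths."""
    total = direct + indirect
    if total == 0:
        raise InvalidParameterError("total effect is zero; shares undefined")
    return direct / total, indirect / total


def fit_mediation(x, m, y, n_boot: int = 2000, seed=None, scale: float = 5.0) -> MediationResult:
    """Fit the X -> M -> Y mediation model with percentile bootstrap CIs."""
    data = pd.DataFrame({"x": x, "m": m, "y": y}).dropna()
    n = len(data)
    if n < 10:
        raise InvalidParameterError(f"need >= 10 complete cases, got {n}")
    xv, mv, yv = (data[c].to_numpy(dtype=float) for c in ("x", "m", "y"))
    for name, v in (("x", xv), ("m", mv), ("y", yv)):
        if np.std(v) == 0:
            raise DegenerateDesignError(f"variable {name} has zero variance")
    a, b, c_prime = _mediation_paths(xv, mv, yv)
    indirect, total = a * b, c_prime + a * b
    share_direct, share_indirect = effect_shares(c_prime, indirect)

    def _z(v):
        return (v - v.mean()) / v.std(ddof=1)

    sa, sb, sc = _mediation_paths(_z(xv), _z(mv), _z(yv))
    standardized = {
        "a": sa, "b": sb, "c_prime": sc, "indirect": sa * sb, "total": sc + sa * sb,
    }

    rng = np.random.default_rng(seed)
    boots = {k: np.empty(n_boot) for k in ("a", "b", "c_prime", "indirect", "total")}
    idx_all = np.arange(n)
    for i in range(n_boot):
        idx = rng.choice(idx_all, size=n, replace=True)
        ba, bb, bc = _mediation_paths(xv[idx], mv[idx], yv[idx])
        boots["a"][i], boots["b"][i], boots["c_prime"][i] = ba, bb, bc
        boots["indirect"][i] = ba * bb
        boots["total"][i] = bc + ba * bb
    ci = {k: tuple(np.percentile(v, [2.5, 97.5])) for k, v in boots.items()}
    boot_se = {k: float(np.std(v, ddof=1)) for k, v in boots.items()}
    per_scale = {
        "direct": c_prime * scale,
        "indirect": indirect * scale,
        "total": total * scale,
        "direct_ci": tuple(scale * np.array(ci["c_prime"])),
        "indirect_ci": tuple(scale * np.array(ci["indirect"])),
        "total_ci": tuple(scale * np.array(ci["total"])),
    }
    return MediationResult(
        a, b, c_prime, indirect, total, share_indirect, share_direct,
        ci, boot_se, standardized, per_scale, scale, n, n_boot,
    )


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root mean square error of approximation for a structural model.

    Zero for a saturated (df = 0) model by construction.
    """
    if df == 0:
        return 0.0
    return float(np.sqrt(max(chi2 / df - 1.0, 0.0) / (n - 1)))


def fit_mediation_no_direct(x, m, y) -> dict:
    """Mediation model with the direct path dropped (one df of misfit).

    The misfit chi-square is the likelihood-ratio statistic of omitting the
    exposure from the outcome equation, n*ln(RSS_restricted/RSS_full);
    RMSEA follows from (chi2, df=1, n).
    """
    data = pd.DataFrame({"x": x, "m": m, "y": y}).dropna()
    n = len(data)
    xv, mv, yv = (data[c].to_numpy(dtype=float) for c in ("x", "m", "y"))
    one = np.ones(n)
    full = np.column_stack([one, xv, mv])
    restr = np.column_stack([one, mv])
    rss_full = float(np.sum((yv - full @ np.linalg.lstsq(full, yv, rcond=None)[0]) ** 2))
    rss_restr = float(np.sum((yv - restr @ np.linalg.lstsq(restr, yv, rcond=None)[0]) ** 2))
    chi2 = n * np.log(rss_restr / rss_full)
    return {"chi2": float(chi2), "df": 1, "n": n, "rmsea": rmsea(chi2, 1, n)}


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------


@dataclass
class LMMResult:
    fe_params: pd.Series
    fe_bse: pd.Series
    fe_pvalues: pd.Series
    var_group: float
    var_resid: float
    llf: float
    grouping: str
    converged: bool
    vc_variances: dict = field(default_factory=dict)


def fit_lmm_random_intercept(
    df: pd.DataFrame,
    response: str,
    fixed,
    group: str,
    nested: str | None = None,
) -> LMMResult:
    """REML random-intercept linear mixed model.

    ``fixed`` is a list of fixed-effect column names (patsy terms are
    allowed). ``group`` names the top grouping factor (subject); an
    optional ``nested`` factor adds a nested random intercept as a
    variance component within each group.
    """
    fixed = list(fixed)
    cols = [response, group] + ([nested] if nested else [])
    data = df.dropna(subset=[c for c in cols if c in df.columns]).copy()
    groups = data[group]
    if groups.nunique() < 2:
        raise DegenerateDesignError(
            "random intercept unidentifiable with fewer than 2 groups"
        )
    formula = f"{response} ~ " + (" + ".join(fixed) if fixed else "1")
    vc_formula = {"nested": f"0 + C({nested})"} if nested else None
    model = smf.mixedlm(formula, data=data, groups=groups, vc_formula=vc_formula)
    fit = None
    # boundary cases (between-group variance ~ 0) can break gradient-based
    # optimizers; fall back to derivative-free searches until one converges
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "powell", "nm"):
            try:
                trial = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if fit is None:
                fit = trial
            if trial.converged:
                fit = trial
                break
    if fit is None:
        raise DegenerateDesignError("mixed-model REML optimization failed")
    var_group = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    vc = {}
    if vc_formula:
        vc = {k: float(v) for k, v in zip(model.exog_vc.names, np.atleast_1d(fit.vcomp))}
    k_fe = len(fit.fe_params)
    return LMMResult(
        fe_params=fit.fe_params,
        fe_bse=fit.bse[:k_fe],
        fe_pvalues=fit.pvalues[:k_fe],
        var_group=var_group,
        var_resid=float(fit.scale),
        llf=float(fit.llf),
        grouping=group + (f"/{nested}" if nested else ""),
        converged=bool(fit.converged),
        vc_variances=vc,
    )


@dataclass
class BaseToApexResult:
    lmm: LMMResult
    contrasts: dict  # slice -> fixed-effect estimate vs basal
    pairwise: pd.DataFrame  # paired t-tests with Holm-adjusted p


def base_to_apex_analysis(slice_table: pd.DataFrame) -> BaseToApexResult:
    """Slice-level MBF gradient: LMM with basal reference + paired tests.

    ``slice_table`` has columns ``subject_id, slice, mbf`` with slice in
    {basal, mid, apical}; per-subject slice means are expected (or raw
    segments, which are averaged per subject and slice first).
    """
    tbl = (
        slice_table.groupby(["subject_id", "slice"], observed=True)["mbf"].mean().reset_index()
    )
    if tbl["subject_id"].nunique() < 2:
        raise DegenerateDesignError(
            "random intercept unidentifiable with a single subject"
        )
    if tbl["slice"].nunique() < 2:
        raise DegenerateDesignError("need at least two slice levels")
    tbl["slice"] = pd.Categorical(tbl["slice"], categories=["basal", "mid", "apical"])
    lmm = fit_lmm_random_intercept(
        tbl, "mbf", ["C(slice, Treatment('basal'))"], group="subject_id"
    )
    contrasts = {
        name.split("T.")[-1].rstrip("]"): float(val)
        for name, val in lmm.fe_params.items()
        if "slice" in name
    }
    wide = tbl.pivot(index="subject_id", columns="slice", values="mbf")
    pairs, raw_p, diffs = [], [], []
    levels = [s for s in ("basal", "mid", "apical") if s in wide.columns]
    for i, s1 in enumerate(levels):
        for s2 in levels[i + 1 :]:
            paired = wide[[s1, s2]].dropna()
            delta = (paired[s2] - paired[s1]).to_numpy()
            if np.ptp(delta) == 0:
                # zero-variance differences: the t statistic is undefined;
                # identical slices carry no evidence, a constant offset is
                # unambiguous
                p = 1.0 if delta.mean() == 0 else 0.0
            else:
                _, p = stats.ttest_rel(paired[s2], paired[s1])
            pairs.append(f"{s2}-{s1}")
            raw_p.append(float(p))
            diffs.append(float(delta.mean()))
    pairwise = pd.DataFrame(
        {"pair": pairs, "mean_diff": diffs, "p_raw": raw_p, "p_holm": holm_adjust(raw_p)}
    )
    return BaseToApexResult(lmm, contrasts, pairwise)


# ---------------------------------------------------------------------------
# Multiplicity, logistic model, power
# ---------------------------------------------------------------------------


def holm_adjust(p_values):
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class LogisticResult:
    odds_ratio: float
    ci: tuple
    slope: float
    slope_se: float
    p_value: float
    n: int


def logistic_lge(ecv_pct, lge_flags) -> LogisticResult:
    """Logistic regression of a binary LGE flag on ECV (%); OR per 1% ECV."""
    data = pd.DataFrame({"ecv": ecv_pct, "lge": lge_flags}).dropna()
    y = data["lge"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise SeparationError("both outcome classes must be present")
    pos, neg = data.loc[y == 1, "ecv"], data.loc[y == 0, "ecv"]
    if pos.min() > neg.max() or pos.max() < neg.min():
        raise SeparationError("complete separation: ECV ranges of the classes do not overlap")
    x = sm.add_constant(data["ecv"].to_numpy())
    try:
        fit = sm.Logit(y, x).fit(disp=False, maxiter=200)
    except PerfectSeparationError as exc:  # pragma: no cover - guarded above
        raise SeparationError(str(exc)) from exc
    slope, se = float(fit.params[1]), float(fit.bse[1])
    if not np.isfinite(se) or abs(slope) > 50:
        raise SeparationError("quasi-separation: unstable logistic estimates")
    ci = (float(np.exp(slope - 1.959964 * se)), float(np.exp(slope + 1.959964 * se)))
    return LogisticResult(float(np.exp(slope)), ci, slope, se, float(fit.pvalues[1]), len(data))


def power_two_sample_t(n_per_group: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Exact two-sided two-sample t-test power from the noncentral t."""
    if n_per_group < 2:
        raise InvalidParameterError("need n >= 2 per group")
    if sd <= 0:
        raise InvalidParameterError("sd must be positive")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    df = 2 * n_per_group - 2
    nc = delta / (sd * np.sqrt(2.0 / n_per_group))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    return float(power)
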