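"""Longitudinal and cross-sectional cohort statistics for expansion indices.

The analyses mirror the standard toolkit for a longitudinal biomarker
measured across clinic visits:

* per-individual **expansion rate** (ER): ordinary least-squares slope of EI
  on age across visits, in EI units per year; the intercept is the
  theoretical EI at birth;
* a **linear mixed-effects model** of EI on age x (CAG)n x disease group
  (full factorial fixed effects, random intercept per individual, REML),
  with age and (CAG)n mean-centered by group on first-visit characteristics
  so that per-group slopes describe a "mean individual" of each group;
* per-group **slope estimates with SEs**, a Type II Wald chi-square test of
  the three-way interaction, and all pairwise slope contrasts adjusted by
  Tukey's studentized-range method;
* **Pearson correlations** (r and the regression-slope p value) of EI/ER
  against germline repeat length and severity;
* **residualized comparisons by disease status**: EI residuals after
  within-group regression on age and (CAG)n (ER residuals on (CAG)n alone),
  compared between premanifest/manifest or preataxic/ataxic carriers with
  two-sided Wilcoxon rank-sum tests;
* descriptive n / mean / sample-SD tables.

Degrees of freedom for slope tests and contrasts use the large-sample
residual df of the mixed model; a Kenward-Roger small-sample correction is
not available in the host stack, and at cohort sizes of ~180 individuals the
difference is immaterial.  The substitution is logged once per fit.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from cagmosaic.errors import (
    InsufficientDataError,
    RankDeficientError,
    UndefinedCorrelationError,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05  # two-sided significance level used throughout


@dataclass(frozen=True)
class ERResult:
    """Per-individual OLS regression of EI on age."""

    individual_id: str
    slope: float  # expansion rate, EI per year
    intercept: float  # theoretical EI at birth
    n_visits: int


@dataclass
class LMMFit:
    """Fitted mixed-effects model of EI on age x (CAG)n x group."""

    fixed_effects: pd.DataFrame  # coef, se, z, p per fixed-effect term
    random_intercept_var: float
    wald_interaction: dict  # statistic, df, p for the three-way interaction
    group_slopes: pd.DataFrame  # group, slope, se, df, t, p (slope vs 0)
    centering: pd.DataFrame  # per-group first-visit means used for centering
    df_resid: float
    groups: tuple[str, ...]
    fe_params: pd.Series = field(repr=False, default=None)
    fe_cov: pd.DataFrame = field(repr=False, default=None)
    result: object = field(repr=False, default=None)


def _as_visit_frame(visits) -> pd.DataFrame:
    if isinstance(visits, pd.DataFrame):
        return visits
    return pd.DataFrame([vars(v) if not isinstance(v, dict) else v for v in visits])


def expansion_rate(visits, individual_id: str | None = None) -> ERResult:
    """OLS slope (ER, EI/year) and intercept (EI at birth) for one individual.

    ``visits`` is a DataFrame (columns ``age``, ``ei``) or a sequence of
    visit records.  At least two visits at distinct ages with finite EI are
    required.
    """
    df = _as_visit_frame(visits)
    df = df[np.isfinite(df["age"]) & np.isfinite(df["ei"])]
    if individual_id is None:
        ids = df["individual_id"].unique() if "individual_id" in df.columns else ["?"]
        individual_id = str(ids[0])
    ages = df["age"].to_numpy(dtype=float)
    eis = df["ei"].to_numpy(dtype=float)
    if len(np.unique(ages)) < 2:
        raise InsufficientDataError(
            f"individual {individual_id!r}: expansion rate needs >= 2 visits "
            f"at distinct ages, got {len(np.unique(ages))}"
        )
    slope, intercept = np.polyfit(ages, eis, 1)
    return ERResult(
        individual_id=individual_id,
        slope=float(slope),
        intercept=float(intercept),
        n_visits=len(ages),
    )


def expansion_rates(visits: pd.DataFrame) -> pd.DataFrame:
    """ER for every individual with >= 2 visits at distinct ages.

    Individuals with a single visit are excluded (slope is not estimable).
    """
    rows = []
    for ind, sub in visits.groupby("individual_id"):
        if sub["age"].nunique() < 2:
            continue
        er = expansion_rate(sub, individual_id=str(ind))
        row = {
            "individual_id": er.individual_id,
            "er": er.slope,
            "ei_at_birth": er.intercept,
            "n_visits": er.n_visits,
        }
        for col in ("gene", "group", "cag_n"):
            if col in sub.columns:
                row[col] = sub[col].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed-effects model


def _first_visit_centering(df: pd.DataFrame, group_col: str) -> pd.DataFrame:
    first = (
        df.sort_values("age")
        .groupby("individual_id", as_index=False)
        .first()[["individual_id", group_col, "age", "cag_n"]]
    )
    cent = first.groupby(group_col).agg(
        mean_age_first_visit=("age", "mean"), mean_cag=("cag_n", "mean")
    )
    return cent


def fit_lmm(visits: pd.DataFrame, group_col: str = "group") -> LMMFit:
    """Fit the random-intercept model of EI on age x (CAG)n x group.

    Fixed effects are the full factorial of centered age, centered (CAG)n
    and the disease group; the random part is an intercept per individual;
    estimation is REML.  Age and (CAG)n are mean-centered *by group on the
    characteristics at first visit*, so each group's slope is evaluated for
    an individual with that group's average first-visit age and repeat
    length.

    A singular fit (random-intercept variance estimated at zero) is
    downgraded to a warning, not a failure.
    """
    df = visits.copy()
    required = {"individual_id", group_col, "age", "cag_n", "ei"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"visit table is missing columns {sorted(missing)}")
    if df[group_col].nunique() < 2:
        raise InsufficientDataError("the mixed model needs >= 2 disease groups")

    cent = _first_visit_centering(df, group_col)
    df = df.join(cent, on=group_col)
    df["age_c"] = df["age"] - df["mean_age_first_visit"]
    df["cag_c"] = df["cag_n"] - df["mean_cag"]
    df["_grp"] = df[group_col].astype(str)

    model = smf.mixedlm(
        "ei ~ age_c * cag_c * C(_grp)", data=df, groups=df["individual_id"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)

    re_var = float(result.cov_re.iloc[0, 0])
    if re_var <= 1e-10:
        logger.warning(
            "random-intercept variance estimated at ~0 (singular fit); "
            "fixed effects equal pooled OLS"
        )

    fe = result.fe_params
    fe_cov = result.cov_params().loc[fe.index, fe.index]
    n_obs = len(df)
    df_resid = n_obs - len(fe)
    logger.info(
        "slope tests use large-sample residual df = %d (no Kenward-Roger "
        "correction available)",
        df_resid,
    )

    groups = tuple(sorted(df["_grp"].unique()))

    def slope_vector(g: str) -> pd.Series:
        L = pd.Series(0.0, index=fe.index)
        L["age_c"] = 1.0
        key = f"age_c:C(_grp)[T.{g}]"
        if key in L.index:
            L[key] = 1.0
        return L

    rows = []
    for g in groups:
        L = slope_vector(g)
        est = float(L @ fe)
        se = float(np.sqrt(L @ fe_cov @ L))
        t = est / se
        p = 2 * st.t.sf(abs(t), df_resid)
        rows.append({"group": g, "slope": est, "se": se, "df": df_resid, "t": t, "p": p})
    group_slopes = pd.DataFrame(rows)

    # Type II Wald chi-square for the highest-order (three-way) interaction:
    # with all lower-order terms present this is the joint test of its
    # coefficients.
    inter = [n for n in fe.index if n.count(":") == 2]
    Lm = np.zeros((len(inter), len(fe)))
    for i, name in enumerate(inter):
        Lm[i, fe.index.get_loc(name)] = 1.0
    beta = fe.to_numpy()
    V = fe_cov.to_numpy()
    lb = Lm @ beta
    stat = float(lb @ np.linalg.solve(Lm @ V @ Lm.T, lb))
    wald = {
        "statistic": stat,
        "df": len(inter),
        "p": float(st.chi2.sf(stat, len(inter))),
    }

    fixed_effects = pd.DataFrame(
        {
            "coef": fe,
            "se": np.sqrt(np.clip(np.diag(fe_cov), 0, None)),
            "z": fe / np.sqrt(np.clip(np.diag(fe_cov), 1e-300, None)),
        }
    )
    fixed_effects["p"] = 2 * st.norm.sf(np.abs(fixed_effects["z"]))

    return LMMFit(
        fixed_effects=fixed_effects,
        random_intercept_var=re_var,
        wald_interaction=wald,
        group_slopes=group_slopes,
        centering=cent,
        df_resid=df_resid,
        groups=groups,
        fe_params=fe,
        fe_cov=fe_cov,
        result=result,
    )


def compare_group_slopes(fit: LMMFit) -> pd.DataFrame:
    """All pairwise differences of per-group EI-vs-age slopes.

    Family-wise adjustment uses the single-step Tukey method over the family
    of group slopes: for a pair with difference ``d`` and standard error
    ``se``, ``q = |d| / se * sqrt(2)`` is referred to the studentized-range
    distribution with ``k`` = number of groups and the model's residual df.
    A contrast of a group with itself is identically 0.
    """
    fe, cov = fit.fe_params, fit.fe_cov
    k = len(fit.groups)

    def vec(g: str) -> pd.Series:
        L = pd.Series(0.0, index=fe.index)
        L["age_c"] = 1.0
        key = f"age_c:C(_grp)[T.{g}]"
        if key in L.index:
            L[key] = 1.0
        return L

    rows = []
    for g1, g2 in itertools.combinations(fit.groups, 2):
        L = vec(g1) - vec(g2)
        diff = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        q = abs(diff) / se * math.sqrt(2.0)
        p = float(st.studentized_range.sf(q, k, fit.df_resid))
        rows.append(
            {
                "contrast": f"{g1} - {g2}",
                "estimate": diff,
                "se": se,
                "q": q,
                "p_tukey": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlations, residualization, status comparisons


def correlate(x, y) -> tuple[float, float]:
    """Pearson r and the two-sided p value of the regression slope.

    The t test of the OLS slope is identical to the t test of r, so a single
    ``pearsonr`` call provides both.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r, p = st.pearsonr(x, y)
    return float(r), float(p)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                bad.append(names[j])
            else:
                kept.append(j)
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def residualize(
    df: pd.DataFrame,
    value_col: str,
    covariate_cols: Sequence[str],
    group_col: str = "group",
) -> pd.DataFrame:
    """Within-group OLS residuals of ``value_col`` on ``covariate_cols``.

    Used to correct first-visit EI for age and (CAG)n, and ER for (CAG)n,
    before comparing disease-status classes.  Residuals within each group
    sum to zero (regression with intercept).
    """
    out = df.copy()
    res_col = f"residual_{value_col}"
    out[res_col] = np.nan
    for g, sub in df.groupby(group_col):
        mask = sub[[value_col, *covariate_cols]].notna().all(axis=1)
        sub = sub[mask]
        if len(sub) <= len(covariate_cols) + 1:
            raise InsufficientDataError(
                f"group {g!r}: need more than {len(covariate_cols) + 1} "
                f"complete rows to residualize, got {len(sub)}"
            )
        X = sm.add_constant(sub[list(covariate_cols)].to_numpy(dtype=float))
        _check_rank(X, ["const", *covariate_cols])
        y = sub[value_col].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out.loc[sub.index, res_col] = y - X @ beta
    return out


def quadratic_age_test(
    df: pd.DataFrame,
    value_col: str,
    group_col: str = "group",
    covariate_cols: Sequence[str] = ("age", "cag_n"),
) -> pd.DataFrame:
    """Wald test of an added age^2 term in the within-group regression.

    Reported per group for model checking only; the quadratic term is never
    auto-selected into the residualization.
    """
    rows = []
    for g, sub in df.groupby(group_col):
        sub = sub[sub[[value_col, *covariate_cols]].notna().all(axis=1)]
        X = sub[list(covariate_cols)].astype(float).copy()
        X["age_sq"] = X["age"] ** 2
        model = sm.OLS(sub[value_col].astype(float), sm.add_constant(X)).fit()
        rows.append(
            {
                "group": g,
                "coef_age_sq": model.params["age_sq"],
                "p_age_sq": model.pvalues["age_sq"],
            }
        )
    return pd.DataFrame(rows)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution for small samples without ties and the
    normal approximation with tie correction otherwise.  Returns the
    Mann-Whitney U statistic of the first sample and the two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and len(pooled) <= 25) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_status(
    df: pd.DataFrame,
    value_col: str,
    status_col: str,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group Wilcoxon rank-sum comparison of a residual by status class.

    Groups where one status class is empty are skipped with a warning.
    """
    rows = []
    for g, sub in df.groupby(group_col):
        sub = sub[sub[[value_col, status_col]].notna().all(axis=1)]
        classes = sorted(sub[status_col].unique())
        if len(classes) != 2:
            logger.warning(
                "group %r: need two status classes, found %r; skipped", g, classes
            )
            continue
        a = sub.loc[sub[status_col] == classes[0], value_col]
        b = sub.loc[sub[status_col] == classes[1], value_col]
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "group": g,
                "class_a": classes[0],
                "class_b": classes[1],
                "n_a": len(a),
                "n_b": len(b),
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Severity and descriptive statistics


def severity(sara: float, disease_duration: float) -> float:
    """Severity score: SARA points per year of disease.

    Returns NaN (flagged via a warning) when the duration is not positive.
    """
    if disease_duration is None or not disease_duration > 0:
        logger.warning(
            "severity undefined for duration %r; record flagged as missing",
            disease_duration,
        )
        return float("nan")
    return float(sara) / float(disease_duration)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def describe(
    values: Iterable[float] | pd.Series | pd.DataFrame,
    by: str | Sequence[str] | None = None,
    value_col: str | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """n / mean / sample-SD table, rounded half away from zero.

    ``values`` is a plain sequence (one summary row) or a DataFrame grouped
    by ``by``.  The SD uses the n-1 denominator and is reported as missing
    for singleton groups.
    """

    def _one(vals) -> dict:
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        n = len(arr)
        if n == 0:
            return {"n": 0, "mean": float("nan"), "sd": float("nan")}
        mean = round_half_up(float(np.mean(arr)), decimals)
        sd = (
            round_half_up(float(np.std(arr, ddof=1)), decimals)
            if n > 1
            else float("nan")
        )
        return {"n": n, "mean": mean, "sd": sd}

    if isinstance(values, pd.DataFrame):
        if value_col is None:
            raise ValueError("value_col is required for DataFrame input")
        if by is None:
            return pd.DataFrame([_one(values[value_col])])
        rows = []
        for keys, sub in values.groupby(by):
            if not isinstance(keys, tuple):
                keys = (keys,)
            by_cols = [by] if isinstance(by, str) else list(by)
            rows.append({**dict(zip(by_cols, keys)), **_one(sub[value_col])})
        return pd.DataFrame(rows)
    return pd.DataFrame([_one(values)])
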