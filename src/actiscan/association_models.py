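"""Survey-weighted per-window association models.

For each hourly window the participant's mean MIMS is cut into quintiles
(quintile 1 = least active = reference) and entered as indicator terms in a
weighted logistic (prevalent diabetes) or linear (log glycaemic marker)
regression, adjusted for the study covariate set. The trend p value refits
the model with the quintile index (1-5) as a single continuous regressor and
reports its Wald p value.

Point estimates are the weighted maximum-likelihood solution (probability
weights). Variances are design-based Taylor linearisation when stratum/PSU
identifiers are available, otherwise a weight-robust sandwich. Confidence
intervals and Wald p values use Student-t quantiles with design degrees of
freedom (PSUs minus strata) under the Taylor variance, normal quantiles
under the sandwich.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError, UsageError
from .hourly_features import CLOCK_PREFIX, REL_PREFIX, assign_quintiles
from .outcomes_covariates import CATEGORICAL_LEVELS, model_covariate_columns

MIN_N = 50
Z95 = stats.norm.ppf(0.975)


def _critical_value(df: int | None) -> float:
    """95% two-sided quantile: design-df t for Taylor variances, else normal."""
    if df is not None and df > 0:
        return float(stats.t.ppf(0.975, df))
    return float(Z95)


def _wald_p(z: float, df: int | None) -> float:
    if df is not None and df > 0:
        return float(2 * stats.t.sf(abs(z), df))
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class SurveyDesign:
    """Survey weights with optional stratum/PSU identifiers.

    All three are aligned to the analysis frame by participant_id. Weights
    must be strictly positive; a PSU column requires a stratum column.
    """

    weights: pd.Series
    stratum: pd.Series | None = None
    psu: pd.Series | None = None

    def __post_init__(self):
        if (self.weights <= 0).any() or self.weights.isna().any():
            raise DataError("survey weights must be positive and non-missing")
        if self.psu is not None and self.stratum is None:
            raise DataError("a PSU identifier requires a stratum identifier")

    def subset(self, ids) -> "SurveyDesign":
        return SurveyDesign(
            weights=self.weights.loc[ids],
            stratum=None if self.stratum is None else self.stratum.loc[ids],
            psu=None if self.psu is None else self.psu.loc[ids],
        )


def build_design_matrix(covariates: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Expand the covariate frame into a numeric design matrix (no constant).

    Categoricals are dummy-coded against their fixed first level; continuous
    columns pass through as float.
    """
    parts = []
    for col in columns:
        if col in CATEGORICAL_LEVELS:
            cat = pd.Categorical(covariates[col], categories=CATEGORICAL_LEVELS[col])
            dummies = pd.get_dummies(cat, prefix=col, drop_first=True, dtype=float)
            dummies.index = covariates.index
            parts.append(dummies)
        else:
            parts.append(covariates[col].astype(float))
    if not parts:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(parts, axis=1)


def _taylor_cov(X: np.ndarray, score: np.ndarray, info: np.ndarray, stratum, psu) -> np.ndarray:
    """Design-based linearised covariance from per-observation score rows.

    ``score`` holds w_i (y_i - mu_i) x_i per row. PSU totals are centred
    within stratum with the n_h/(n_h - 1) finite-cluster correction.
    """
    bread = np.linalg.pinv(info)
    df = pd.DataFrame(score)
    df["_stratum"] = np.asarray(stratum)
    df["_psu"] = np.asarray(psu)
    meat = np.zeros((X.shape[1], X.shape[1]))
    for _, g in df.groupby("_stratum", observed=True):
        z = g.drop(columns=["_stratum", "_psu"]).groupby(g["_psu"], observed=True).sum().to_numpy()
        n_h = z.shape[0]
        if n_h < 2:
            continue
        d = z - z.mean(axis=0, keepdims=True)
        meat += (n_h / (n_h - 1)) * d.T @ d
    return bread @ meat @ bread


def _fit_glm(y, X, w, family, design: SurveyDesign | None, variance: str):
    """Weighted GLM fit returning (params, cov, converged).

    Columns are rescaled to unit root-mean-square internally (continuous
    covariates such as total activity live on scales of 1e4, which otherwise
    makes the sandwich numerically indefinite) and results mapped back.
    """
    Xa = np.asarray(X, dtype=float)
    rms = np.sqrt(np.mean(Xa**2, axis=0))
    rms[rms == 0] = 1.0
    Xs = Xa / rms

    model = sm.GLM(np.asarray(y, dtype=float), Xs, family=family, var_weights=np.asarray(w, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    params_s = np.asarray(res.params)
    mu = np.asarray(res.fittedvalues)
    wv = np.asarray(w, dtype=float)
    resid = np.asarray(y, dtype=float) - mu
    score = (wv * resid)[:, None] * Xs
    if isinstance(family, sm.families.Binomial):
        irls_w = wv * mu * (1.0 - mu)
    else:
        irls_w = wv
    info = (Xs * irls_w[:, None]).T @ Xs

    use_taylor = (
        variance == "taylor" and design is not None and design.stratum is not None and design.psu is not None
    )
    df = None
    if use_taylor:
        cov_s = _taylor_cov(Xs, score, info, design.stratum, design.psu)
        clusters = pd.MultiIndex.from_arrays([np.asarray(design.stratum), np.asarray(design.psu)])
        df = len(clusters.unique()) - pd.Index(design.stratum).nunique()
    else:
        bread = np.linalg.pinv(info)
        cov_s = bread @ (score.T @ score) @ bread
    params = params_s / rms
    cov = cov_s / np.outer(rms, rms)
    return params, cov, bool(res.converged), df


def _check_estimable(params, cov, exposure_idx) -> bool:
    """Finite exposure estimates/SEs of plausible magnitude (no separation)."""
    se_sq = np.diag(cov)[exposure_idx]
    p = params[exposure_idx]
    return bool(np.all(np.isfinite(p)) and np.all(se_sq > 0) and np.all(np.isfinite(se_sq)) and np.all(np.abs(p) < 15))


def _quintile_design(q: pd.Series, covariates: pd.DataFrame, cov_cols: list[str], continuous: bool):
    if continuous:
        expo = q.astype(float).rename("quintile_index").to_frame()
    else:
        expo = pd.get_dummies(q.astype(int), prefix="q", drop_first=True, dtype=float)
    Xc = build_design_matrix(covariates, cov_cols)
    X = pd.concat([expo, Xc], axis=1)
    X.insert(0, "const", 1.0)
    return X, list(expo.columns)


def _fit_quintile_model(
    outcome: pd.Series,
    quintile: pd.Series,
    covariates: pd.DataFrame,
    design: SurveyDesign,
    family,
    variance: str,
    window_id: str,
) -> pd.DataFrame:
    """Shared machinery for the logistic and linear per-window fits.

    Returns one row per non-reference quintile (2-5) plus the implicit
    reference row, with the trend p value repeated on every row. The
    ``status`` column is ``ok``, ``degenerate`` (exposure has one level),
    ``too_few`` or ``non_estimable``.
    """
    frame = pd.concat([outcome.rename("_y"), quintile.rename("_q"), covariates], axis=1)
    frame = frame.dropna()
    n_used = len(frame)
    base = {
        "window_id": window_id,
        "n_used": n_used,
        "p_trend": np.nan,
        "stratum_label": "all",
        "sensitivity_label": "main",
    }

    def _status_rows(status: str) -> pd.DataFrame:
        rows = [dict(base, quintile=qq, estimate=np.nan, ci_low=np.nan, ci_high=np.nan, status=status) for qq in range(1, 6)]
        return pd.DataFrame(rows)

    is_binary = isinstance(family, sm.families.Binomial)
    if n_used < MIN_N or (is_binary and frame["_y"].nunique() < 2):
        return _status_rows("too_few")
    if frame["_q"].nunique() < 2:
        warnings.warn(f"window {window_id}: degenerate exposure (single quintile); skipped")
        return _status_rows("degenerate")

    sub_design = design.subset(frame.index)
    w = sub_design.weights
    cov_cols = model_covariate_columns(covariates)

    try:
        X, expo_cols = _quintile_design(frame["_q"], frame[covariates.columns], cov_cols, continuous=False)
        params, cov, converged, df = _fit_glm(frame["_y"], X, w, family, sub_design, variance)
        Xt, _ = _quintile_design(frame["_q"], frame[covariates.columns], cov_cols, continuous=True)
        pt_params, pt_cov, _, _ = _fit_glm(frame["_y"], Xt, w, family, sub_design, variance)
    except (np.linalg.LinAlgError, ValueError):
        return _status_rows("non_estimable")
    expo_idx = [i for i, c in enumerate(X.columns) if c in expo_cols]
    if not converged or not _check_estimable(params, cov, expo_idx):
        return _status_rows("non_estimable")

    names = list(X.columns)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    crit = _critical_value(df)
    k = list(Xt.columns).index("quintile_index")
    trend_se = float(np.sqrt(max(pt_cov[k, k], 0.0)))
    if not np.isfinite(pt_params[k]) or trend_se <= 0:
        return _status_rows("non_estimable")
    z = pt_params[k] / trend_se
    p_trend = _wald_p(z, df)
    base["p_trend"] = p_trend

    rows = [dict(base, quintile=1, estimate=0.0, ci_low=0.0, ci_high=0.0, status="ok")]
    for qq in range(2, 6):
        name = f"q_{qq}"
        if name in names:
            j = names.index(name)
            est = params[j]
            rows.append(
                dict(base, quintile=qq, estimate=est, ci_low=est - crit * se[j], ci_high=est + crit * se[j], status="ok")
            )
        else:  # quintile level absent after complete-case filtering
            rows.append(dict(base, quintile=qq, estimate=np.nan, ci_low=np.nan, ci_high=np.nan, status="level_absent"))
    out = pd.DataFrame(rows)
    out["trend_estimate"] = pt_params[k]
    out["trend_se"] = trend_se
    return out


def fit_weighted_logistic(
    outcome: pd.Series,
    quintile: pd.Series,
    covariates: pd.DataFrame,
    design: SurveyDesign,
    variance: str = "robust",
    window_id: str = "w",
) -> pd.DataFrame:
    """Per-quintile log-odds ratios vs quintile 1 for a binary outcome.

    ``estimate`` is the log-OR; exponentiate for the OR scale. The reference
    quintile row carries estimate 0 (OR exactly 1).
    """
    return _fit_quintile_model(
        outcome, quintile, covariates, design, sm.families.Binomial(), variance, window_id
    )


def fit_weighted_linear(
    outcome: pd.Series,
    quintile: pd.Series,
    covariates: pd.DataFrame,
    design: SurveyDesign,
    variance: str = "robust",
    window_id: str = "w",
) -> pd.DataFrame:
    """Per-quintile beta coefficients vs quintile 1 for a log-scale outcome."""
    return _fit_quintile_model(
        outcome, quintile, covariates, design, sm.families.Gaussian(), variance, window_id
    )


def trend_test(
    outcome: pd.Series,
    quintile: pd.Series,
    covariates: pd.DataFrame,
    design: SurveyDesign,
    family: str = "logistic",
    variance: str = "robust",
) -> dict:
    """Wald test of the continuous quintile-index (1-5) coefficient.

    Returns estimate, se, ci bounds and p value; the test is invariant to
    affine recoding of the index.
    """
    fam = sm.families.Binomial() if family == "logistic" else sm.families.Gaussian()
    frame = pd.concat([outcome.rename("_y"), quintile.rename("_q"), covariates], axis=1).dropna()
    if len(frame) < MIN_N:
        raise DataError("too few complete cases for the trend test")
    sub_design = design.subset(frame.index)
    cov_cols = model_covariate_columns(covariates)
    X, _ = _quintile_design(frame["_q"], frame[covariates.columns], cov_cols, continuous=True)
    params, cov, _, df = _fit_glm(frame["_y"], X, sub_design.weights, fam, sub_design, variance)
    k = list(X.columns).index("quintile_index")
    est, se = float(params[k]), float(np.sqrt(max(cov[k, k], 0.0)))
    if not np.isfinite(est) or se <= 0 or abs(est) > 15:
        raise DataError("trend coefficient not estimable (degenerate or separated design)")
    crit = _critical_value(df)
    z = est / se
    return {
        "estimate": est,
        "se": se,
        "ci_low": est - crit * se,
        "ci_high": est + crit * se,
        "p": _wald_p(z, df),
        "n_used": len(frame),
    }


def run_window_scan(
    features: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    design: SurveyDesign,
    framing: str = "relative",
    family: str = "logistic",
    variance: str = "robust",
) -> pd.DataFrame:
    """Fit the quintile model for each of the 24 hourly windows of a framing.

    ``features`` is the wide per-participant feature matrix indexed by
    participant_id; quintiles are recomputed per window on the analysis
    sample. Non-estimable or degenerate windows appear in the grid with their
    status flag rather than being dropped.
    """
    if framing == "relative":
        prefix = REL_PREFIX
    elif framing == "clock":
        prefix = CLOCK_PREFIX
    else:
        raise UsageError(f"unknown framing {framing!r}")
    fam_is_logistic = family == "logistic"
    fit = fit_weighted_logistic if fam_is_logistic else fit_weighted_linear

    grids = []
    for k in range(1, 25):
        col = f"{prefix}{k:02d}"
        vals = features[col]
        q = assign_quintiles(vals)
        res = fit(outcome, q, covariates, design, variance=variance, window_id=f"{framing}_{k:02d}")
        res["framing"] = framing
        res["window_index"] = k
        grids.append(res)
    return pd.concat(grids, ignore_index=True)


def run_subgroups_and_sensitivity(
    features: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    design: SurveyDesign,
    strata: pd.DataFrame,
    sleep_duration_h: pd.Series,
    framing: str = "relative",
    family: str = "logistic",
    variance: str = "robust",
) -> dict[str, pd.DataFrame]:
    """Subgroup trend scans and the extreme-sleep sensitivity scan.

    Subgroups model the quintile index as continuous (one trend estimate per
    window per stratum, the power-preserving choice); the chronotype split
    uses the in-sample median weekend sleep midpoint. The sensitivity analysis
    re-runs the full main scan excluding sleep duration <= 4 h or >= 10 h.

    ``strata`` columns (all optional): gender, age, race_ethnicity,
    weekend_midpoint. Returns a dict of labelled result frames.
    """
    prefix = REL_PREFIX if framing == "relative" else CLOCK_PREFIX
    out: dict[str, pd.DataFrame] = {}

    def _trend_scan(mask: pd.Series, label: str) -> pd.DataFrame:
        ids = mask[mask].index
        rows = []
        for k in range(1, 25):
            col = f"{prefix}{k:02d}"
            try:
                q = assign_quintiles(features.loc[ids, col])
                res = trend_test(outcome.loc[ids], q, covariates.loc[ids], design.subset(ids), family, variance)
                res.update(window_index=k, framing=framing, stratum_label=label, status="ok")
            except DataError:
                res = {"window_index": k, "framing": framing, "stratum_label": label, "status": "not_estimable"}
            rows.append(res)
        return pd.DataFrame(rows)

    subgroup_defs = {}
    if "gender" in strata.columns:
        subgroup_defs["gender_men"] = strata["gender"] == "men"
        subgroup_defs["gender_women"] = strata["gender"] == "women"
    if "age" in strata.columns:
        subgroup_defs["age_lt_65"] = strata["age"] < 65
        subgroup_defs["age_ge_65"] = strata["age"] >= 65
    if "race_ethnicity" in strata.columns:
        for lvl in ["nh_white", "nh_black", "hispanic"]:
            subgroup_defs[f"race_{lvl}"] = strata["race_ethnicity"] == lvl
    if "weekend_midpoint" in strata.columns:
        med = strata["weekend_midpoint"].median()
        subgroup_defs["chronotype_early"] = strata["weekend_midpoint"] < med
        subgroup_defs["chronotype_late"] = strata["weekend_midpoint"] >= med
    if sleep_duration_h is not None:
        subgroup_defs["sleep_lt_7h"] = sleep_duration_h < 7
        subgroup_defs["sleep_ge_7h"] = sleep_duration_h >= 7

    frames = []
    for label, mask in subgroup_defs.items():
        frames.append(_trend_scan(mask.fillna(False), label))
    if frames:
        out["subgroups"] = pd.concat(frames, ignore_index=True)

    keep = ~((sleep_duration_h <= 4) | (sleep_duration_h >= 10))
    ids = keep[keep.fillna(False)].index
    sens = run_window_scan(
        features.loc[ids], outcome.loc[ids], covariates.loc[ids], design.subset(ids), framing, family, variance
    )
    sens["sensitivity_label"] = "excl_extreme_sleep"
    out["sensitivity"] = sens
    return out


def or_scale(grid: pd.DataFrame) -> pd.DataFrame:
    """Add OR-scale columns (exp of estimate and CI bounds) to a logistic grid."""
    out = grid.copy()
    for src, dst in [("estimate", "or_"), ("ci_low", "or_ci_low"), ("ci_high", "or_ci_high")]:
        out[dst] = np.exp(out[src])
    return out


def table2_layout(grid: pd.DataFrame, logistic: bool = True) -> pd.DataFrame:
    """Serialise a scan grid into the wide window x quintile report layout."""
    g = grid[grid["quintile"] > 1].copy()
    if logistic:
        txt = [
            f"{np.exp(e):.2f} ({np.exp(lo):.2f}, {np.exp(hi):.2f})" if np.isfinite(e) else "-"
            for e, lo, hi in zip(g["estimate"], g["ci_low"], g["ci_high"])
        ]
    else:
        txt = [
            f"{e:.3f} ({lo:.3f}, {hi:.3f})" if np.isfinite(e) else "-"
            for e, lo, hi in zip(g["estimate"], g["ci_low"], g["ci_high"])
        ]
    g["cell"] = txt
    wide = g.pivot(index="window_index", columns="quintile", values="cell")
    wide.columns = [f"Q{int(c)}" for c in wide.columns]
    wide.insert(0, "Q1", "Ref")
    ptr = grid.groupby("window_index")["p_trend"].first()
    wide["p_trend"] = ptr
    return wide.reset_index()
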