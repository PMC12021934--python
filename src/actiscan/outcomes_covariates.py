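"""Diabetes outcome derivation, glycaemic-marker harmonisation and covariate
coding.

Diabetes is defined as HbA1c >= 48 mmol/mol (6.5%) or a self-reported
diagnosis. Fasting insulin from the 2013-2014 laboratory protocol is mapped
onto the 2011-2012 scale with the published regression calibration before any
derived quantity uses it. HOMA-IR uses the standard HOMA1-IR formula,
glucose[mmol/l] x insulin[uU/ml] / 22.5 (so glucose 22.5 with insulin 1 gives
exactly 1). All continuous glycaemic outcomes are modelled on the natural-log
scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

HBA1C_DIABETES_MMOL_MOL = 48.0

CYCLES = ("2011-2012", "2013-2014")

#: Regression calibration mapping 2013-2014 fasting insulin onto the
#: 2011-2012 laboratory scale: 10^(1.024 * log10(x) - 0.0802).
INSULIN_CAL_SLOPE = 1.024
INSULIN_CAL_INTERCEPT = -0.0802

HOMA_IR_DENOMINATOR = 22.5

BMI_LEVELS = ["lt_18.5", "18.5_to_lt_25", "25_to_lt_30", "ge_30"]
INCOME_LEVELS = ["lt_20k", "20k_to_44.9k", "45k_to_74.9k", "ge_75k"]
EDUCATION_LEVELS = ["lt_high_school", "high_school", "some_college", "college_grad"]
SMOKING_LEVELS = ["never", "former", "current"]
ALCOHOL_LEVELS = ["lt_1_per_week", "1_per_week_to_lt_1_per_day", "ge_1_per_day"]
GENDER_LEVELS = ["men", "women"]
MARITAL_LEVELS = ["not_married", "married"]
SLEEP_DURATION_LEVELS = ["lt_7", "7_to_9", "gt_9"]

#: Categorical covariates with their closed level sets; the first level of
#: each is the regression reference.
CATEGORICAL_LEVELS = {
    "gender": GENDER_LEVELS,
    "race_ethnicity": ["nh_white", "nh_black", "hispanic", "other"],
    "education": EDUCATION_LEVELS,
    "income": INCOME_LEVELS,
    "marital": MARITAL_LEVELS,
    "smoking": SMOKING_LEVELS,
    "alcohol": ALCOHOL_LEVELS,
    "bmi_cat": BMI_LEVELS,
    "sleep_duration_cat": SLEEP_DURATION_LEVELS,
}

CONTINUOUS_COVARIATES = ["age", "energy_kj", "sleep_midpoint_cont", "total_pa"]


def derive_diabetes(hba1c, selfreport):
    """Diabetes status from HbA1c and self-report (True/False/NA).

    True when HbA1c >= 48 mmol/mol or self-report is positive; False only when
    both are known negative; otherwise unknown (NA). Accepts scalars or
    aligned Series (NaN/None = missing).
    """
    h = pd.Series(hba1c, dtype=float) if not isinstance(hba1c, pd.Series) else hba1c.astype(float)
    s = pd.Series(selfreport) if not isinstance(selfreport, pd.Series) else selfreport
    s = s.astype(object)

    positive = (h >= HBA1C_DIABETES_MMOL_MOL).fillna(False) | (s == True)  # noqa: E712
    negative = (h < HBA1C_DIABETES_MMOL_MOL).fillna(False) & (s == False)  # noqa: E712
    out = pd.Series(pd.NA, index=h.index, dtype=object)
    out[positive] = True
    out[negative & ~positive] = False
    if np.isscalar(hba1c) or hba1c is None:
        return out.iloc[0]
    return out


def harmonize_insulin(value, cycle):
    """Map fasting insulin (uU/ml) onto the 2011-2012 laboratory scale.

    Identity for the 2011-2012 cycle; the published log10-linear calibration
    for 2013-2014. Values must be strictly positive.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v[np.isfinite(v)] <= 0):
        raise DomainError("fasting insulin must be > 0")
    if isinstance(cycle, str):
        if cycle not in CYCLES:
            raise DomainError(f"unknown survey cycle {cycle!r}")
        if cycle == "2011-2012":
            return value
        out = 10.0 ** (INSULIN_CAL_SLOPE * np.log10(v) + INSULIN_CAL_INTERCEPT)
        return float(out) if np.isscalar(value) else out
    cyc = np.asarray(cycle, dtype=object)
    bad = ~np.isin(cyc, CYCLES)
    if bad.any():
        raise DomainError(f"unknown survey cycle {cyc[bad][0]!r}")
    out = np.where(cyc == "2013-2014", 10.0 ** (INSULIN_CAL_SLOPE * np.log10(v) + INSULIN_CAL_INTERCEPT), v)
    return out


def compute_homa_ir(fasting_glucose, fasting_insulin):
    """HOMA1-IR = glucose[mmol/l] x insulin[uU/ml] / 22.5 (insulin harmonised)."""
    g = np.asarray(fasting_glucose, dtype=float)
    i = np.asarray(fasting_insulin, dtype=float)
    if np.any(g[np.isfinite(g)] <= 0) or np.any(i[np.isfinite(i)] <= 0):
        raise DomainError("fasting glucose and insulin must be > 0")
    out = g * i / HOMA_IR_DENOMINATOR
    return float(out) if np.isscalar(fasting_glucose) and np.isscalar(fasting_insulin) else out


def transform_outcomes(panel: pd.DataFrame) -> pd.DataFrame:
    """Add natural-log columns for the four continuous glycaemic outcomes.

    Input columns (when present): fasting_glucose, fasting_insulin, homa_ir,
    ogtt_2h_glucose; output adds ``log_<name>``. Non-positive values are a
    domain error; missing values stay missing.
    """
    out = panel.copy()
    for col in ["fasting_glucose", "fasting_insulin", "homa_ir", "ogtt_2h_glucose"]:
        if col not in out.columns:
            continue
        v = out[col].astype(float)
        if (v <= 0).any():
            raise DomainError(f"{col} must be > 0 for the log transform")
        out[f"log_{col}"] = np.log(v)
    return out


def bmi_category(bmi) -> pd.Series:
    """BMI (kg/m^2) bands <18.5 / 18.5-<25 / 25-<30 / >=30."""
    b = pd.Series(bmi, dtype=float)
    if (b <= 0).any():
        raise DataError("BMI must be positive")
    cat = pd.Series(pd.NA, index=b.index, dtype=object)
    cat[b < 18.5] = BMI_LEVELS[0]
    cat[(b >= 18.5) & (b < 25)] = BMI_LEVELS[1]
    cat[(b >= 25) & (b < 30)] = BMI_LEVELS[2]
    cat[b >= 30] = BMI_LEVELS[3]
    return cat


def income_category(income_usd) -> pd.Series:
    """Household income bands <20k / 20k-44.9k / 45k-74.9k / >=75k (US$)."""
    v = pd.Series(income_usd, dtype=float)
    cat = pd.Series(pd.NA, index=v.index, dtype=object)
    cat[v < 20_000] = INCOME_LEVELS[0]
    cat[(v >= 20_000) & (v < 45_000)] = INCOME_LEVELS[1]
    cat[(v >= 45_000) & (v < 75_000)] = INCOME_LEVELS[2]
    cat[v >= 75_000] = INCOME_LEVELS[3]
    return cat


def encode_covariates(raw: pd.DataFrame, include_bmi: bool = True) -> pd.DataFrame:
    """Normalise raw participant fields into the model covariate frame.

    Numeric ``bmi`` / ``income_usd`` columns are banded when the categorical
    columns are absent; categorical columns are validated against the closed
    level sets and cast to ordered categoricals whose first level is the
    regression reference. Continuous covariates pass through unchanged.
    Rows with missing model covariates are retained here; the model layer is
    complete-case within each analysis.
    """
    out = raw.copy()
    if "bmi_cat" not in out.columns and "bmi" in out.columns:
        out["bmi_cat"] = bmi_category(out["bmi"])
    if "income" not in out.columns and "income_usd" in out.columns:
        out["income"] = income_category(out["income_usd"])

    for col, levels in CATEGORICAL_LEVELS.items():
        if col not in out.columns:
            continue
        bad = out[col].dropna()[~out[col].dropna().isin(levels)]
        if len(bad):
            raise DataError(f"unknown level {bad.iloc[0]!r} in covariate {col!r}")
        out[col] = pd.Categorical(out[col], categories=levels)

    if not include_bmi and "bmi_cat" in out.columns:
        out = out.drop(columns=["bmi_cat"])
    return out


def model_covariate_columns(frame: pd.DataFrame, include_bmi: bool = True) -> list[str]:
    """The adjustment set actually present in ``frame``, in model order."""
    cols = ["age", "gender", "race_ethnicity", "education", "income", "marital", "smoking", "alcohol"]
    if include_bmi:
        cols.append("bmi_cat")
    cols += ["energy_kj", "sleep_duration_cat", "sleep_midpoint_cont", "total_pa"]
    return [c for c in cols if c in frame.columns]
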