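"""Linear methylation clocks, age acceleration, and group comparisons.

A linear methylation clock predicts age from a weighted sum of CpG beta
values: x = intercept + sum_i w_i * beta_i, followed by an inverse
calibration transform.  The multi-tissue-clock calibration is piecewise
log-linear about an "adult age" A (typically 20 years):

    F(age)  = log((age + 1) / (A + 1))   for age <= A
            = (age - A) / (A + 1)        for age >  A

and the predictor reports age = F^-1(x).  Age acceleration (AgeAccel)
is the residual of predicted epigenetic age regressed on chronological
age over all samples pooled: positive means epigenetically older than
expected.  Group comparisons use an unpaired t-test on residuals
(Welch by default) and a sequential regression comparison: a
group-by-age interaction tests slope equality, and — with a common
slope retained — the group main effect tests intercept equality.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ClockModel",
    "AgeAccelResult",
    "transform_age",
    "inverse_transform_age",
    "apply_clock",
    "age_accel",
    "compare_groups",
    "compare_regressions",
    "cell_fraction",
    "run_clock_analysis",
]

logger = logging.getLogger(__name__)

MAX_MISSING_FRACTION = 0.05  # clock CpGs allowed to be mean-imputed


@dataclass(frozen=True)
class ClockModel:
    """Coefficients of any linear methylation clock.

    transform is "identity" or "horvath_piecewise"; adult_age is the
    calibration knot of the piecewise transform (years).
    """

    name: str
    coefficients: dict[str, float]
    intercept: float
    transform: str = "horvath_piecewise"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("clock needs at least one coefficient")
        if self.transform not in ("identity", "horvath_piecewise"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.adult_age <= 0:
            raise ValueError("adult_age must be positive")

    def coefficient_order(self) -> list[str]:
        return list(self.coefficients)

    @classmethod
    def from_files(cls, coef_csv, header_json) -> "ClockModel":
        """Load from a (probe_id, weight) CSV plus a JSON header with
        name, intercept, transform and (optionally) adult_age."""
        coefs = pd.read_csv(coef_csv)
        if not {"probe_id", "weight"} <= set(coefs.columns):
            raise ValueError("coefficient file needs columns probe_id, weight")
        if coefs["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in coefficient file")
        header = json.loads(Path(header_json).read_text())
        return cls(
            name=header.get("name", Path(str(coef_csv)).stem),
            coefficients=dict(zip(coefs["probe_id"], coefs["weight"].astype(float))),
            intercept=float(header["intercept"]),
            transform=header.get("transform", "horvath_piecewise"),
            adult_age=float(header.get("adult_age", 20.0)),
        )

    def to_files(self, coef_csv, header_json) -> None:
        pd.DataFrame(
            {"probe_id": list(self.coefficients), "weight": list(self.coefficients.values())}
        ).to_csv(coef_csv, index=False)
        Path(header_json).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "intercept": self.intercept,
                    "transform": self.transform,
                    "adult_age": self.adult_age,
                },
                indent=2,
            )
        )


def transform_age(age, adult_age: float = 20.0):
    """Calibration transform F: age (years) -> linear clock scale."""
    age = np.asarray(age, dtype=float)
    if (age < 0).any():
        raise ValueError("ages must be nonnegative")
    return np.where(
        age <= adult_age,
        np.log1p(age) - np.log1p(adult_age),
        (age - adult_age) / (adult_age + 1.0),
    )


def inverse_transform_age(x, adult_age: float = 20.0):
    """Inverse calibration F^-1: linear clock scale -> age (years)."""
    x = np.asarray(x, dtype=float)
    return np.where(
        x <= 0,
        (1.0 + adult_age) * np.exp(x) - 1.0,
        (1.0 + adult_age) * x + adult_age,
    )


def apply_clock(betas: pd.DataFrame, clock: ClockModel) -> pd.Series:
    """Predicted epigenetic age (years) per sample.

    betas: CpG probes (rows) x samples (columns), values in [0, 1].
    Missing clock probes: more than 5% is an error; up to 5% are imputed
    per sample with the mean of the available clock-probe betas, with a
    warning.
    """
    probes = clock.coefficient_order()
    present = [p for p in probes if p in betas.index]
    missing = [p for p in probes if p not in betas.index]
    frac_missing = len(missing) / len(probes)
    if frac_missing > MAX_MISSING_FRACTION:
        raise ValueError(
            f"{len(missing)}/{len(probes)} clock CpGs missing from the beta "
            f"matrix (> {MAX_MISSING_FRACTION:.0%})"
        )
    mat = betas.loc[present].astype(float)
    if missing:
        warnings.warn(
            f"{len(missing)} clock CpGs missing; imputed with per-sample "
            "mean of available clock probes",
            stacklevel=2,
        )
        fill = mat.mean(axis=0)
        for p in missing:
            mat.loc[p] = fill
        mat = mat.loc[probes]
    w = pd.Series(clock.coefficients)
    x = clock.intercept + mat.mul(w.loc[mat.index], axis=0).sum(axis=0)
    if clock.transform == "horvath_piecewise":
        ages = inverse_transform_age(x.to_numpy(), clock.adult_age)
    else:
        ages = x.to_numpy(dtype=float)
    return pd.Series(ages, index=betas.columns, name="dnam_age")


def age_accel(dnam_ages, chrono_ages) -> np.ndarray:
    """AgeAccel residuals: OLS of epigenetic on chronological age, pooled.

    Positive residual = epigenetically older than expected for the
    chronological age.
    """
    dnam = np.asarray(dnam_ages, dtype=float)
    chrono = np.asarray(chrono_ages, dtype=float)
    if dnam.shape != chrono.shape or dnam.size < 3:
        raise ValueError("need >= 3 paired ages")
    if np.ptp(chrono) == 0:
        raise ValueError("chronological ages are all equal; regression degenerate")
    fit = sm.OLS(dnam, sm.add_constant(chrono)).fit()
    return np.asarray(fit.resid)


@dataclass
class TTestResult:
    t: float
    p: float
    group_means: dict[str, float]
    n: dict[str, int]


def compare_groups(residuals, labels, equal_var: bool = False) -> TTestResult:
    """Unpaired two-sample t-test (Welch by default) on AgeAccel residuals."""
    res = np.asarray(residuals, dtype=float)
    lab = np.asarray(labels)
    names = sorted(pd.unique(lab))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    a, b = (res[lab == g] for g in names)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(
        t=float(t),
        p=float(p),
        group_means={names[0]: float(a.mean()), names[1]: float(b.mean())},
        n={names[0]: len(a), names[1]: len(b)},
    )


@dataclass
class RegressionComparison:
    slope_p: float
    intercept_p: float
    interaction_coef: float
    group_coef: float


def compare_regressions(chrono, dnam, labels) -> RegressionComparison:
    """Sequential comparison of per-group age regressions.

    First tests the group x age interaction (slope equality) in the full
    model; then, in the common-slope model, tests the group main effect
    (intercept equality).
    """
    df = pd.DataFrame(
        {
            "age": np.asarray(chrono, dtype=float),
            "dnam": np.asarray(dnam, dtype=float),
            "group": np.asarray(labels),
        }
    )
    names = sorted(df["group"].unique())
    if len(names) != 2:
        raise ValueError("need exactly two groups")
    for g in names:
        sub = df[df["group"] == g]
        if len(sub) < 3:
            raise ValueError(f"group {g} needs n >= 3")
        if sub["age"].nunique() < 2:
            raise ValueError(f"group {g} has a collinear (constant-age) design")
    df["g"] = (df["group"] == names[1]).astype(float)
    df["age_g"] = df["age"] * df["g"]
    X_full = sm.add_constant(df[["age", "g", "age_g"]])
    full = sm.OLS(df["dnam"], X_full).fit()
    X_common = sm.add_constant(df[["age", "g"]])
    common = sm.OLS(df["dnam"], X_common).fit()
    return RegressionComparison(
        slope_p=float(full.pvalues["age_g"]),
        intercept_p=float(common.pvalues["g"]),
        interaction_coef=float(full.params["age_g"]),
        group_coef=float(common.params["g"]),
    )


def cell_fraction(betas: pd.DataFrame, model: ClockModel) -> pd.Series:
    """Estimated epithelial cell fraction from a 2-CpG signature model.

    Linear predictor on the two probe betas, clipped into [0, 1] with a
    warning when clipping occurs.  Coefficients are user-supplied.
    """
    if len(model.coefficients) != 2:
        raise ValueError("cell-fraction model must have exactly two CpGs")
    missing = [p for p in model.coefficients if p not in betas.index]
    if missing:
        raise ValueError(f"cell-fraction CpGs missing from beta matrix: {missing}")
    w = pd.Series(model.coefficients)
    pred = model.intercept + betas.loc[w.index].astype(float).mul(w, axis=0).sum(axis=0)
    if ((pred < 0) | (pred > 1)).any():
        warnings.warn("cell fractions outside [0, 1] were clipped", stacklevel=2)
    return pred.clip(0.0, 1.0).rename("epithelial_fraction")


@dataclass
class AgeAccelResult:
    per_sample: pd.DataFrame  # sample_id, group, age, dnam_age, residual
    ttest: TTestResult
    regression: RegressionComparison

    def summary(self) -> dict:
        return {
            "group_mean_residuals": self.ttest.group_means,
            "n": self.ttest.n,
            "t_statistic": self.ttest.t,
            "p_two_tailed": self.ttest.p,
            "slope_equality_p": self.regression.slope_p,
            "intercept_equality_p": self.regression.intercept_p,
        }


def run_clock_analysis(
    betas: pd.DataFrame, sheet: pd.DataFrame, clock: ClockModel
) -> AgeAccelResult:
    """Clock stage end-to-end: predict ages, AgeAccel, group tests.

    sheet needs columns sample_id, group, age; samples must be columns
    of the beta matrix.
    """
    missing = set(sheet["sample_id"]) - set(betas.columns)
    if missing:
        raise ValueError(f"samples missing from beta matrix: {sorted(missing)}")
    ordered = betas[sheet["sample_id"].tolist()]
    dnam = apply_clock(ordered, clock)
    residuals = age_accel(dnam.to_numpy(), sheet["age"].to_numpy())
    ttest = compare_groups(residuals, sheet["group"].to_numpy())
    reg = compare_regressions(
        sheet["age"].to_numpy(), dnam.to_numpy(), sheet["group"].to_numpy()
    )
    per_sample = pd.DataFrame(
        {
            "sample_id": sheet["sample_id"].to_numpy(),
            "group": sheet["group"].to_numpy(),
            "age": sheet["age"].to_numpy(),
            "dnam_age": dnam.to_numpy(),
            "residual": residuals,
        }
    )
    return AgeAccelResult(per_sample=per_sample, ttest=ttest, regression=reg)
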