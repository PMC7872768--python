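"""Confound regression of regional volumes and group demographic statistics.

Age and gender effects are removed from every regional volume by ordinary
least squares on the design ``[1, age, gender]``, fitted once across all
subjects pooled (both groups together): fitting per group would remove
group-mean structure inconsistently before network construction. The
residual matrix feeds the covariance-network stage.

Demographic group comparisons use the Student pooled-variance two-sample
t-test for continuous variables and the uncorrected Pearson chi-square for
2x2 sex tables, the conventions of standard clinical statistics software.
A Kolmogorov-Smirnov normality check is available as an advisory only; it
never switches the test.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CohortTable, RegionalVolumeTable, ValidationError

__all__ = [
    "ConfoundModel",
    "regress_confounds",
    "two_sample_t",
    "chi_square_2x2",
    "ks_normality",
    "demographic_table",
]


@dataclasses.dataclass
class ConfoundModel:
    """Per-ROI OLS fit of volumes on [intercept, covariates...].

    ``residuals`` (subjects x ROI) are orthogonal to every design column and
    have (numerically) zero column means; they are the "normalized" regional
    volumes used for covariance networks.
    """

    design_columns: list[str]
    design: np.ndarray            # (n, k)
    coefficients: np.ndarray      # (n_roi, k)
    residuals: np.ndarray         # (n, n_roi)
    roi_labels: list[str]
    subject_ids: list[str]

    def residuals_for_group(self, cohort: CohortTable, level) -> np.ndarray:
        mask = cohort.subjects_in_group(level)
        return self.residuals[mask]


def regress_confounds(
    volumes: RegionalVolumeTable,
    cohort: CohortTable,
    covariates: Sequence[str] = ("age", "gender"),
) -> ConfoundModel:
    """Regress covariates out of every ROI volume; pooled across groups.

    Raises
    ------
    ValidationError
        If the design is rank deficient; the message names the offending
        column (e.g. a constant gender column).
    """
    cohort = cohort.aligned_to(volumes)
    n = volumes.n_subjects
    cols = ["intercept"] + list(covariates)
    X = np.column_stack(
        [np.ones(n)] + [cohort.data[c].to_numpy(dtype=float) for c in covariates]
    )
    for k, name in enumerate(cols[1:], start=1):
        if np.ptp(X[:, k]) == 0:
            raise ValidationError(f"design column {name!r} is constant; model is rank deficient")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a column that is a linear combination of the preceding ones
        for k in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : k + 1]) < k + 1:
                raise ValidationError(f"design column {cols[k]!r} makes the model rank deficient")
    beta, *_ = np.linalg.lstsq(X, volumes.volumes, rcond=None)
    residuals = volumes.volumes - X @ beta
    return ConfoundModel(
        design_columns=cols,
        design=X,
        coefficients=beta.T,
        residuals=residuals,
        roi_labels=list(volumes.roi_labels),
        subject_ids=list(volumes.subject_ids),
    )


class TTestResult(NamedTuple):
    t: float
    p: float
    df: float


def two_sample_t(x, y) -> TTestResult:
    """Student pooled-variance two-sample t (two-tailed), df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValidationError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue), float(len(x) + len(y) - 2))


class ChiSquareResult(NamedTuple):
    chi2: float
    p: float
    df: int


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValidationError("table must hold nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("zero marginal total")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(float(chi2), float(p), int(dof))


def ks_normality(x) -> tuple[float, float]:
    """Advisory Kolmogorov-Smirnov test against N(mean, sd); never gates tests."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    stat, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return float(stat), float(p)


def demographic_table(cohort: CohortTable, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Group means (SD) with pooled t for continuous variables, chi-square for sex.

    Variables present in only one group (clinical scores of the patient arm)
    are summarised without a test. Returns one row per variable.
    """
    g1, g2 = cohort.group_levels[:2] if len(cohort.group_levels) == 2 else (cohort.group_levels[0],) * 2
    m1 = cohort.subjects_in_group(g1)
    m2 = cohort.subjects_in_group(g2)
    if variables is None:
        variables = ["age"] + [
            c for c in cohort.clinical_columns
            if pd.api.types.is_numeric_dtype(cohort.data[c])
        ]
    rows = []
    for var in variables:
        x = cohort.data[var].to_numpy(dtype=float)[m1]
        y = cohort.data[var].to_numpy(dtype=float)[m2]
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        row = {
            "variable": var,
            f"mean_{g1}": np.mean(x) if len(x) else np.nan,
            f"sd_{g1}": np.std(x, ddof=1) if len(x) > 1 else np.nan,
            f"mean_{g2}": np.mean(y) if len(y) else np.nan,
            f"sd_{g2}": np.std(y, ddof=1) if len(y) > 1 else np.nan,
            "statistic": np.nan,
            "p": np.nan,
            "test": "",
        }
        if len(x) >= 2 and len(y) >= 2 and not (np.ptp(x) == 0 and np.ptp(y) == 0):
            t, p, _ = two_sample_t(x, y)
            row.update(statistic=t, p=p, test="t")
        rows.append(row)
    # sex as a 2x2 chi-square
    gender = cohort.data["gender"].to_numpy(dtype=float)
    tab = np.array(
        [
            [(gender[m1] == 1).sum(), (gender[m1] == 0).sum()],
            [(gender[m2] == 1).sum(), (gender[m2] == 0).sum()],
        ]
    )
    if np.all(tab.sum(axis=0) > 0) and np.all(tab.sum(axis=1) > 0):
        chi2, p, _ = chi_square_2x2(tab)
        rows.append(
            {
                "variable": "gender",
                f"mean_{g1}": tab[0, 0], f"sd_{g1}": np.nan,
                f"mean_{g2}": tab[1, 0], f"sd_{g2}": np.nan,
                "statistic": chi2, "p": p, "test": "chi2",
            }
        )
    return pd.DataFrame(rows)
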