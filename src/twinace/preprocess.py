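"""Data-cleaning stage: covariate residualization, log transforms, outlier
rules and descriptive statistics.

The cleaning pipeline for a measure is: outlier handling on the raw scale,
ordinary least-squares residualization on age and sex, then (optionally) a
natural-log transform of positivity-shifted residuals.  Skewness is the
adjusted Fisher-Pearson sample coefficient; kurtosis is sample *excess*
kurtosis (a normal sample converges to 0), so mildly platykurtic measures can
print negative values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_model import MALE, TwinDataset
from .errors import DegenerateDataError, DegenerateDesignError, DomainError

__all__ = [
    "DescriptiveRow",
    "residualize",
    "log_transform",
    "replace_listed_outliers",
    "remove_3sd_outliers",
    "describe",
    "clean_measure",
]


@dataclass(frozen=True)
class DescriptiveRow:
    """Summary statistics for one measure (observed values only)."""

    n: int
    mean: float
    sd: float
    median: float
    range: tuple[float, float]
    skew: float
    kurtosis: float


def _sex_indicator(sex) -> np.ndarray:
    sex = np.asarray(sex)
    if sex.dtype.kind in "biuf":
        return sex.astype(float)
    return (sex == MALE).astype(float)


def residualize(values, age, sex) -> np.ndarray:
    """OLS residuals of ``values`` on intercept + age + male indicator.

    Computed on complete cases; rows with a missing value (or covariate)
    get NaN residuals.  A covariate that does not vary is dropped from the
    design; if neither covariate varies the design is degenerate.
    """
    y = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    male = _sex_indicator(sex)
    if not (len(y) == len(age) == len(male)):
        raise ValueError("values, age and sex must have equal length")
    mask = ~(np.isnan(y) | np.isnan(age) | np.isnan(male))
    if mask.sum() < 3:
        raise DegenerateDataError("need at least 3 complete cases")

    cols = [np.ones(mask.sum())]
    for cov in (age[mask], male[mask]):
        if np.ptp(cov) > 0:
            cols.append(cov)
    if len(cols) == 1:
        raise DegenerateDesignError("degenerate design: constant age and single sex")
    X = np.column_stack(cols)
    res = sm.OLS(y[mask], X).fit()
    out = np.full(len(y), np.nan)
    out[mask] = res.resid
    return out


def log_transform(values, offset: float = 0.0) -> np.ndarray:
    """Elementwise ln(value + offset); NaN passes through."""
    y = np.asarray(values, dtype=float)
    shifted = y + offset
    bad = np.flatnonzero(~np.isnan(shifted) & (shifted <= 0))
    if bad.size:
        raise DomainError(
            f"log_transform: nonpositive argument {shifted[bad[0]]!r} at index {int(bad[0])}"
        )
    return np.log(shifted)


def replace_listed_outliers(values, threshold: float) -> tuple[np.ndarray, float | None]:
    """Replace values above an absolute raw-scale cutoff by the clean mean.

    Values strictly greater than ``threshold`` are replaced by the mean of the
    non-flagged observed values; the replacement value is returned rounded to
    2 decimals for reporting (None when nothing was flagged).
    """
    y = np.asarray(values, dtype=float).copy()
    observed = ~np.isnan(y)
    flagged = observed & (y > threshold)
    if not flagged.any():
        return y, None
    keep = observed & ~flagged
    if not keep.any():
        raise DegenerateDataError("all observed values exceed the outlier threshold")
    mean = float(y[keep].mean())
    y[flagged] = mean
    return y, round(mean, 2)


def remove_3sd_outliers(values) -> tuple[np.ndarray, int]:
    """Single-pass 3-SD rule: entries strictly beyond mean +/- 3 SD become NaN.

    Mean and SD are computed once on all observed values (not iterated);
    returns the filtered copy and the number removed.  A value exactly at the
    cutoff is retained.
    """
    y = np.asarray(values, dtype=float).copy()
    observed = ~np.isnan(y)
    if observed.sum() < 3:
        raise DegenerateDataError("need at least 3 observed values")
    m = y[observed].mean()
    sd = y[observed].std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero standard deviation")
    out = observed & (np.abs(y - m) > 3 * sd)
    y[out] = np.nan
    return y, int(out.sum())


def describe(values) -> DescriptiveRow:
    """Descriptive statistics over observed values."""
    y = np.asarray(values, dtype=float)
    y = y[~np.isnan(y)]
    if y.size < 2:
        raise DegenerateDataError("need at least 2 observed values")
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant vector: skew/kurtosis undefined")
    return DescriptiveRow(
        n=int(y.size),
        mean=float(y.mean()),
        sd=float(y.std(ddof=1)),
        median=float(np.median(y)),
        range=(float(y.min()), float(y.max())),
        skew=float(stats.skew(y, bias=False)),
        kurtosis=float(stats.kurtosis(y, fisher=True, bias=False)),
    )


def clean_measure(
    dataset: TwinDataset,
    measure: str,
    *,
    replace_above: float | None = None,
    remove_3sd: bool = False,
    log: bool = False,
    log_offset: float = 0.0,
) -> tuple[TwinDataset, dict]:
    """Apply the full cleaning pipeline to one measure.

    Order of operations: raw-scale outlier handling, residualization on age
    and sex, then an optional log transform applied to positivity-shifted
    residuals (shift chosen so the minimum residual maps to ln 1 = 0; the
    shift used is recorded in the returned info dict).
    """
    info: dict = {"measure": measure}
    y = dataset.df[measure].to_numpy(dtype=float)
    if replace_above is not None:
        y, repl = replace_listed_outliers(y, replace_above)
        info["replacement_value"] = repl
    if remove_3sd:
        y, n_removed = remove_3sd_outliers(y)
        info["n_removed_3sd"] = n_removed
    y = residualize(y, dataset.df["age"].to_numpy(), dataset.df["sex"].to_numpy())
    if log:
        shift = log_offset + 1.0 - np.nanmin(y)
        info["log_shift"] = float(shift)
        y = log_transform(y, offset=shift)
    return dataset.with_measure(measure, y), info
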