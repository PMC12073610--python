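"""Statistical layer: per-day t-tests, Pearson correlations on averaged
values, significance cutoffs, and the linear regressions used to estimate
NDVI, PRI and Fv/Fm from RGB indices.

The analysis follows the averaged-value design: ROI values are first
averaged per (species, treatment, day) cell; correlations and regressions
then pair those cell means across treatment arms.  With the default design
a drought analysis pairs control + drought over 6 days (n = 12 cells) and a
salinization analysis pairs control + three NaCl levels (n = 24); the
pooled set over all five arms has n = 30, which is the set used to fit the
calibration regressions.

A correlation is flagged significant when |R| exceeds the two-tailed
critical value at alpha = 0.05 derived from the t distribution with n - 2
degrees of freedom (0.58 at n = 12).  Note that because ExG = 3 g - 1 is an
affine function of g, correlations and R^2 involving ExG and g are
identical by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RGB_INDEX_COLS = ("r", "g", "b", "ExG", "VEG", "VARI")
TARGET_COLS = ("FvFm", "NDVI", "PRI")
VALUE_COLS = RGB_INDEX_COLS + TARGET_COLS

#: Treatment arms entering each correlation analysis.
STRESSOR_SETS = {
    "drought": ("control", "drought"),
    "salinization": ("control", "nacl100", "nacl200", "nacl400"),
    "all": ("control", "drought", "nacl100", "nacl200", "nacl400"),
}

DEFAULT_R2_FLOOR = 0.7


@dataclass(frozen=True)
class CalibrationModel:
    """Per (species, RGB index, target) simple linear regression."""

    species: str
    index: str
    target: str
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def daily_means(records: pd.DataFrame) -> pd.DataFrame:
    """Average ROI values per (species, treatment, day) cell.

    Missing ROI values are dropped; a cell with no finite ROI values stays
    missing (NaN), never zero.
    """
    value_cols = [c for c in VALUE_COLS if c in records.columns]
    if not value_cols:
        raise ValueError("records contain no index columns")
    grouped = (
        records.groupby(["species", "treatment", "day"], sort=True)[value_cols]
        .mean()  # NaNs excluded per column
        .reset_index()
    )
    return grouped


def significance_stars(p: float) -> str:
    """Figure-legend convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ttest_control_vs_treated(control, treated) -> tuple[float, float]:
    """Two-sample Student's t-test (pooled variance), two-tailed.

    Returns (t, p); (nan, nan) when either sample has fewer than two
    values.  The degenerate zero-variance case with differing means is
    flagged as p = 0.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    control = control[np.isfinite(control)]
    treated = treated[np.isfinite(treated)]
    if control.size < 2 or treated.size < 2:
        return (np.nan, np.nan)
    if control.var(ddof=1) == 0 and treated.var(ddof=1) == 0:
        if control.mean() == treated.mean():
            return (0.0, 1.0)
        logger.warning("t-test on zero-variance samples with differing means")
        return (np.inf if control.mean() > treated.mean() else -np.inf, 0.0)
    t, p = stats.ttest_ind(control, treated, equal_var=True)
    return (float(t), float(p))


def welch_ttest(control, treated) -> tuple[float, float]:
    """Welch (unequal-variance) variant, offered as an option."""
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    control = control[np.isfinite(control)]
    treated = treated[np.isfinite(treated)]
    if control.size < 2 or treated.size < 2:
        return (np.nan, np.nan)
    t, p = stats.ttest_ind(control, treated, equal_var=False)
    return (float(t), float(p))


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson(x, y) -> float:
    """Product-moment correlation on pairwise-complete values (n >= 3)."""
    x, y = _paired(x, y)
    if x.size < 3:
        return np.nan
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant input: R undefined
        return np.nan
    return float(stats.pearsonr(x, y).statistic)


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Two-tailed critical |R| at significance ``alpha`` for sample size n.

    r_c = t_c / sqrt(t_c^2 + n - 2) with t_c the (1 - alpha/2) quantile of
    the t distribution on n - 2 degrees of freedom.  At n = 12, alpha=0.05
    this is 0.576 (0.58 to two decimals).
    """
    if n < 3:
        raise ValueError("critical_r requires n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 2
    t_c = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_c / np.sqrt(t_c**2 + df))


def linear_fit(x, y, species: str = "", index: str = "", target: str = "") -> CalibrationModel | None:
    """Ordinary least-squares line y = slope*x + intercept.

    Returns None (missing model) with fewer than 3 complete pairs or zero
    variance in x.  R^2 equals the squared Pearson correlation of (x, y),
    an identity for simple OLS.
    """
    x, y = _paired(x, y)
    if x.size < 3 or np.ptp(x) == 0:
        logger.warning("linear_fit: insufficient data for %s %s~%s", species, target, index)
        return None
    res = stats.linregress(x, y)
    return CalibrationModel(
        species=species, index=index, target=target,
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), pearson_r=float(res.rvalue), n=int(x.size),
    )


def correlation_table(means: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson R of each RGB index with each target, per species and
    stressor set (drought: control+drought cells; salinization: control +
    NaCl cells), with the critical-|R| significance flag."""
    rows = []
    for species, sdf in means.groupby("species"):
        for set_name in ("drought", "salinization"):
            arms = STRESSOR_SETS[set_name]
            sub = sdf[sdf["treatment"].isin(arms)]
            for index in RGB_INDEX_COLS:
                for target in TARGET_COLS:
                    x, y = _paired(sub[index], sub[target])
                    r = pearson(x, y)
                    n = int(x.size)
                    thresh = critical_r(n, alpha) if n >= 3 else np.nan
                    rows.append(
                        {
                            "species": species,
                            "stressor_set": set_name,
                            "index": index,
                            "target": target,
                            "pearson_r": r,
                            "n": n,
                            "critical_r": thresh,
                            "significant": bool(np.isfinite(r) and abs(r) > thresh),
                        }
                    )
    return pd.DataFrame(rows)


def build_calibrations(means: pd.DataFrame, arms: str = "all",
                       r2_floor: float = DEFAULT_R2_FLOOR) -> pd.DataFrame:
    """Fit one linear model per (species, RGB index, target).

    ``arms`` selects the treatment cells entering the fit ("all" pools
    control + drought + salinization, the design used for the calibration
    scatter plots).  Models with R^2 below ``r2_floor`` are kept but
    flagged ``low_r2``.
    """
    if arms not in STRESSOR_SETS:
        raise ValueError(f"unknown stressor set {arms!r}")
    treatments = STRESSOR_SETS[arms]
    rows = []
    for species, sdf in means.groupby("species"):
        sub = sdf[sdf["treatment"].isin(treatments)]
        for index in RGB_INDEX_COLS:
            for target in TARGET_COLS:
                model = linear_fit(sub[index], sub[target], species, index, target)
                if model is None:
                    continue
                rows.append(
                    {
                        "species": species,
                        "index": index,
                        "target": target,
                        "slope": model.slope,
                        "intercept": model.intercept,
                        "r2": model.r2,
                        "pearson_r": model.pearson_r,
                        "n": model.n,
                        "low_r2": model.r2 < r2_floor,
                    }
                )
    return pd.DataFrame(rows)


def estimate(models: pd.DataFrame, species: str, index: str, values) -> pd.DataFrame:
    """Predict NDVI, PRI and Fv/Fm from RGB-index values using fitted models.

    Raises when the model table lacks the requested index for the species.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    sub = models[(models["species"] == species) & (models["index"] == index)]
    if sub.empty:
        raise ValueError(f"no calibration model for index {index!r} (species {species!r})")
    out = pd.DataFrame({"species": species, "index": index, "value": values})
    for _, row in sub.iterrows():
        out[row["target"]] = row["slope"] * values + row["intercept"]
    return out
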