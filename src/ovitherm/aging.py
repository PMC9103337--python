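"""Aging statistics: repeatability, category summaries, regressions.

The air chamber grows as the egg loses water and CO2 through the shell,
so its projected area A_b tracks weight loss — the classical aging
marker.  This module provides

* per-egg per-day repeatability statistics (sample mean, sample standard
  deviation and sd as a percent of the mean, the 68%-coverage summary);
* per-(category, day) summaries of the chamber parameters a, b, c with
  +/-1 sd dispersion bands, plus normalized area A_b/A_b0 and volume
  proxy V_b/V_b0 (normalized to the first test day) and mean weight
  loss;
* polynomial regressions of normalized area (order 2) and normalized
  volume (order 1) against mean weight loss, with R^2.

Standard deviations use the n-1 (sample) denominator.  Measurements
flagged ``fit_failed`` are excluded everywhere and surface as N/A (NaN)
entries rather than being dropped silently.  Weight loss is expressed in
grams relative to each egg's first test day (a percent mode is available
via ``loss_mode``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError, ParameterError, RegressionError
from .sizing import AirChamberMeasurement, Flag
from .thermo_io import Category

__all__ = [
    "AgingRecord",
    "RepeatabilityResult",
    "CategorySummary",
    "RegressionResult",
    "repeatability_stats",
    "normalize_series",
    "records_to_frame",
    "category_summary",
    "fit_regression",
    "plot_summary",
]


@dataclass
class AgingRecord:
    """One egg on one day: identity, weight and its chamber measurement."""

    egg_id: str
    category: Category
    days_since_laying: int
    weight_g: float
    measurement: AirChamberMeasurement

    def __post_init__(self) -> None:
        self.category = Category(self.category)


@dataclass
class RepeatabilityResult:
    """Daily mean and dispersion of repeated area measurements of one egg.

    NaN fields mark the N/A case (< 2 valid repeats).
    """

    egg_id: str
    day: int
    mean_A_b: float
    sd_A_b: float
    sd_percent: float
    n: int

    @property
    def available(self) -> bool:
        return np.isfinite(self.sd_percent)


@dataclass
class CategorySummary:
    """Cross-egg statistics of one size category on one day."""

    category: Category
    day: int
    n: int
    a_mean: float
    a_sd: float
    b_mean: float
    b_sd: float
    c_mean: float
    c_sd: float
    A_mean: float
    V_mean: float
    weight_loss_mean: float


@dataclass
class RegressionResult:
    """Polynomial OLS fit y = beta0 + beta1 x (+ beta2 x^2) with R^2."""

    order: int
    coefficients: tuple[float, ...]
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order + 1:
            raise RegressionError("coefficient count must equal order + 1")

    @property
    def r2_defined(self) -> bool:
        return np.isfinite(self.r_squared)

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coefficients)


def repeatability_stats(values, egg_id: str = "", day: int = 0) -> RepeatabilityResult:
    """Sample mean/sd/sd% of repeated A_b values for one egg-day.

    Non-finite entries (failed fits) are dropped; fewer than 2 valid
    values yields an N/A result, mirroring missing table entries.
    """
    arr = np.asarray(list(values), dtype=np.float64)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return RepeatabilityResult(egg_id, day, np.nan, np.nan, np.nan, int(arr.size))
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return RepeatabilityResult(egg_id, day, mean, sd, 100.0 * sd / mean, int(arr.size))


def normalize_series(values) -> np.ndarray:
    """Divide a day-ordered series by its first (first-test-day) value."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise NormalizationError("empty series")
    if not np.isfinite(arr[0]) or arr[0] <= 0:
        raise NormalizationError("first-day value missing or non-positive")
    return arr / arr[0]


def records_to_frame(records) -> pd.DataFrame:
    """Flatten AgingRecords into a tidy DataFrame (one row per egg-day)."""
    rows = []
    for r in records:
        m = r.measurement
        rows.append(
            {
                "egg_id": r.egg_id,
                "category": Category(r.category).value,
                "day": int(r.days_since_laying),
                "weight_g": r.weight_g,
                "a_mm": m.a_mm,
                "b_mm": m.b_mm,
                "c_mm": m.c_mm,
                "A_b_mm2": m.A_b_mm2,
                "V_proxy_mm3": m.V_proxy_mm3,
                "valid": Flag.FIT_FAILED not in m.flags,
            }
        )
    return pd.DataFrame(rows)


def category_summary(records, loss_mode: str = "grams") -> pd.DataFrame:
    """Per-(category, day) means and sample sds of a, b, c, area and volume.

    ``fit_failed`` rows are excluded.  Weight loss is computed per egg
    relative to its first test day (grams, or percent of the first-day
    weight with ``loss_mode='percent'``) and then averaged across eggs.
    Groups with < 2 valid eggs report NaN sds.  Normalized columns
    ``A_norm``/``V_norm`` divide each category's mean series by its
    first-day mean.
    """
    if loss_mode not in ("grams", "percent"):
        raise ParameterError("loss_mode must be 'grams' or 'percent'")
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if df.empty:
        raise ParameterError("no records to summarize")
    first_w = (
        df.sort_values("day").groupby("egg_id")["weight_g"].first().rename("w0")
    )
    df = df.join(first_w, on="egg_id")
    loss = df["w0"] - df["weight_g"]
    df["weight_loss"] = loss if loss_mode == "grams" else 100.0 * loss / df["w0"]
    valid = df[df["valid"]]
    out = []
    for (cat, day), grp in valid.groupby(["category", "day"], sort=True):
        n = len(grp)

        def _stat(col: str) -> tuple[float, float]:
            vals = grp[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                return np.nan, np.nan
            sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else np.nan
            return float(vals.mean()), sd

        a_mean, a_sd = _stat("a_mm")
        b_mean, b_sd = _stat("b_mm")
        c_mean, c_sd = _stat("c_mm")
        A_mean, _ = _stat("A_b_mm2")
        V_mean, _ = _stat("V_proxy_mm3")
        wl_mean, _ = _stat("weight_loss")
        out.append(
            {
                "category": cat,
                "day": int(day),
                "n": n,
                "a_mean": a_mean,
                "a_sd": a_sd,
                "b_mean": b_mean,
                "b_sd": b_sd,
                "c_mean": c_mean,
                "c_sd": c_sd,
                "A_mean": A_mean,
                "V_mean": V_mean,
                "weight_loss_mean": wl_mean,
            }
        )
    summary = pd.DataFrame(out).sort_values(["category", "day"]).reset_index(drop=True)
    for col, norm in (("A_mean", "A_norm"), ("V_mean", "V_norm")):
        summary[norm] = np.nan
        for cat, grp in summary.groupby("category"):
            summary.loc[grp.index, norm] = normalize_series(grp[col].to_numpy())
    return summary


def fit_regression(x, y, order: int) -> RegressionResult:
    """Ordinary least squares on a polynomial basis, with R^2.

    Order 2 is used for normalized area vs weight loss, order 1 for the
    normalized volume proxy.  Requires at least ``order + 2`` points.
    Zero variance in y leaves R^2 undefined (NaN).
    """
    if order not in (1, 2):
        raise RegressionError("order must be 1 or 2")
    x = np.asarray(list(x), dtype=np.float64)
    y = np.asarray(list(y), dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < order + 2:
        raise RegressionError(f"{x.size} points < required {order + 2} for order {order}")
    coeffs = np.polynomial.polynomial.polyfit(x, y, order)
    yhat = np.polynomial.polynomial.polyval(x, coeffs)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = np.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(
        order=order, coefficients=tuple(float(c) for c in coeffs),
        r_squared=r2, n_points=int(x.size),
    )


def plot_summary(summary: pd.DataFrame, path, parameter: str = "A_norm") -> None:
    """Plot a per-category mean series with +/-1 sd bands (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    sd_col = {"a_mean": "a_sd", "b_mean": "b_sd", "c_mean": "c_sd"}.get(parameter)
    for cat, grp in summary.groupby("category"):
        ax.plot(grp["day"], grp[parameter], marker="o", label=str(cat))
        if sd_col is not None:
            ax.fill_between(
                grp["day"],
                grp[parameter] - grp[sd_col],
                grp[parameter] + grp[sd_col],
                alpha=0.2,
            )
    ax.set_xlabel("days since laying")
    ax.set_ylabel(parameter)
    ax.legend(title="category")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
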