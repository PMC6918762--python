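"""Newtonian heating-curve analysis for model-egg temperature series.

Under constant irradiance an egg whose internal heat redistribution is fast
relative to its surface exchange heats according to Newton's law:

    T(t) = T_f + (T_i − T_f) · exp(−t / Tc),

equivalently y = a·e^{bx} with y = T(t) − T_f, a = T_i − T_f, b = −1/Tc and
x = t. Tc is the *characteristic heating time*: at t = Tc the egg has
completed 1 − e⁻¹ ≈ 63.2% of its total temperature change. The lab protocol
fits this two-parameter model per replicate; the field protocol skips the fit
(convection-dominated materials such as twigs do not follow the model) and
summarizes the final temperature as the mean of the last few records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: field series are cropped here because trailing records were missing in
#: some replicates of the original protocol (20 min at 10 s sampling)
FIELD_CROP_S = 1111.0


@dataclass
class HeatingSeries:
    """A time–temperature record for one replicate of one material."""

    t: np.ndarray  # seconds from start, strictly increasing
    T: np.ndarray  # degrees C
    material: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.t.shape != self.T.shape or self.t.ndim != 1:
            raise ValueError("t and T must be 1-D arrays of equal length")
        if not (np.isfinite(self.t).all() and np.isfinite(self.T).all()):
            raise ValueError("series values must be finite")
        if (np.diff(self.t) <= 0).any():
            raise ValueError("time values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class HeatingFit:
    T_i: float
    T_f: float
    a: float  # = T_i - T_f
    b: float  # 1/s, negative
    Tc: float  # s, = -1/b
    r2: float


@dataclass
class MaterialSummary:
    material: str
    n_replicates: int
    T_final: float  # degrees C
    Tc_mean: float | None = None
    Tc_se: float | None = None
    r2_mean: float | None = None
    reflectance: float | None = None


def read_series_csv(path) -> list[HeatingSeries]:
    """Read a long-format CSV (time_s, temp_C, material, replicate) into series."""
    df = pd.read_csv(path)
    required = {"time_s", "temp_C"}
    if not required <= set(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    if "material" not in df:
        df["material"] = ""
    if "replicate" not in df:
        df["replicate"] = "0"
    out = []
    for (mat, rep), grp in df.groupby(["material", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        out.append(HeatingSeries(t=grp["time_s"].to_numpy(),
                                 T=grp["temp_C"].to_numpy(),
                                 material=str(mat), replicate=str(rep)))
    return out


def fit_heating(series: HeatingSeries, t_f_records: int = 5) -> HeatingFit:
    """Fit y = a·e^{bx} to the temperature series by nonlinear least squares.

    T_f — the temperature reached at the end of the heating run — is estimated
    as the mean of the last ``t_f_records`` records (the same convention the
    field protocol uses for final temperatures; a single record would inject
    its measurement noise as a constant offset into every residual), then
    refined once by subtracting the model-predicted change still remaining
    over those records, so a noiseless exponential is reproduced exactly.
    y = T − T_f is fitted with two free parameters. Initial guesses are
    deterministic: a0 from the first record, b0 from a log-linear regression
    of log|y| on t over the first half of the series, so the fit is
    reproducible for given data.
    """
    if len(series) < 10:
        raise ValueError("need at least 10 samples to fit a heating curve")
    t, T = series.t, series.T
    if T.max() - T.min() <= 0.5:
        raise ValueError("temperature range too small to fit (<= 0.5 degC)")
    k_tail = max(1, min(t_f_records, len(T)))
    T_f = float(T[-k_tail:].mean())
    y = T - T_f
    a0 = float(y[0])
    if a0 == 0.0:
        a0 = float(y[np.argmax(np.abs(y))]) or -1.0

    half = max(2, len(t) // 2)
    yh = y[:half]
    th = t[:half]
    ok = np.abs(yh) > 1e-12
    if ok.sum() >= 2:
        slope = np.polyfit(th[ok], np.log(np.abs(yh[ok])), 1)[0]
        b0 = min(slope, -1e-6)
    else:
        b0 = -1e-3

    def model(x, a, b):
        return a * np.exp(b * x)

    def _fit(y_shifted, p0):
        try:
            popt, _ = optimize.curve_fit(model, t, y_shifted, p0=p0,
                                         maxfev=20000)
        except RuntimeError as err:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"heating fit did not converge (material={series.material!r}, "
                f"replicate={series.replicate!r}): {err}"
            ) from err
        return float(popt[0]), float(popt[1])

    a, b = _fit(y, (a0, b0))
    if b < 0:
        # the tail mean still contains a*mean(e^{bt}) of unfinished change;
        # remove the model's own prediction of it and refit once
        tail = t[-k_tail:]
        T_f = float(T[-k_tail:].mean() - a * np.exp(b * tail).mean())
        y = T - T_f
        a, b = _fit(y, (a, b))
    if b >= 0:
        raise ValueError("not a heating curve: fitted rate b >= 0")
    if a > 0:  # T_i above T_f: the series cools toward equilibrium
        raise ValueError("not a heating curve: temperature decreases (a > 0)")

    resid = y - model(t, a, b)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return HeatingFit(T_i=T_f + a, T_f=T_f, a=a, b=b, Tc=-1.0 / b, r2=r2)


def predict(fit: HeatingFit, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the fitted heating curve at time(s) t."""
    return fit.T_f + fit.a * np.exp(fit.b * np.asarray(t, dtype=float))


def characteristic_fraction(rounded: bool = True) -> float:
    """Fraction (%) of the total temperature change completed at t = Tc.

    100·(1 − e⁻¹) = 63.212...%, conventionally quoted as 63.2%.
    """
    frac = 100.0 * (1.0 - math.exp(-1.0))
    return round(frac, 1) if rounded else frac


def crop_series(series: HeatingSeries, t_max: float = FIELD_CROP_S) -> HeatingSeries:
    """Drop records after ``t_max`` seconds (field protocol: 1111 s)."""
    keep = series.t <= t_max
    return HeatingSeries(t=series.t[keep], T=series.T[keep],
                         material=series.material, replicate=series.replicate)


def summarize_final_temperature(series: HeatingSeries, k: int = 5) -> float:
    """Mean of the last k temperature records (field protocol default k=5)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(series):
        raise ValueError(f"k={k} exceeds series length {len(series)}")
    return float(series.T[-k:].mean())


def _spearman_exact_p(x_rank: np.ndarray, y_rank: np.ndarray, rs_obs: float) -> float:
    """Two-sided permutation p for Spearman's rs by full enumeration."""
    n = len(x_rank)
    xc = x_rank - x_rank.mean()
    denom_x = math.sqrt(float((xc**2).sum()))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        yp = y_rank[list(perm)]
        yc = yp - yp.mean()
        denom_y = math.sqrt(float((yc**2).sum()))
        rs = float((xc * yc).sum()) / (denom_x * denom_y)
        if abs(rs) >= abs(rs_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def reflectance_temperature_correlation(
    summaries: list[MaterialSummary],
) -> tuple[float, float]:
    """Spearman correlation between material reflectance and final temperature.

    Darker materials absorb more sunlight, so the expected sign is negative.
    Ties get average ranks. For n <= 8 the p-value is exact (full permutation
    enumeration); beyond that scipy's asymptotic p is returned.
    """
    mats = [s for s in summaries if s.reflectance is not None]
    if len(mats) < 4:
        raise ValueError("need at least 4 materials with reflectance values")
    refl = np.array([s.reflectance for s in mats], dtype=float)
    temp = np.array([s.T_final for s in mats], dtype=float)
    res = stats.spearmanr(refl, temp)
    rs = float(res.statistic)
    if len(mats) <= 8:
        p = _spearman_exact_p(stats.rankdata(refl), stats.rankdata(temp), rs)
    else:
        p = float(res.pvalue)
    return rs, p


def summarize_materials(
    fits: dict[tuple[str, str], HeatingFit] | None,
    finals: dict[tuple[str, str], float],
    reflectance: dict[str, float] | None = None,
) -> list[MaterialSummary]:
    """Aggregate per-replicate results into per-material summaries.

    ``fits`` may be None for the field protocol where Tc is not estimated.
    """
    materials = sorted({m for m, _ in finals})
    out = []
    for mat in materials:
        t_final = [v for (m, _), v in finals.items() if m == mat]
        summ = MaterialSummary(material=mat, n_replicates=len(t_final),
                               T_final=float(np.mean(t_final)))
        if fits:
            tcs = np.array([f.Tc for (m, _), f in fits.items() if m == mat])
            if tcs.size:
                summ.Tc_mean = float(tcs.mean())
                summ.Tc_se = float(tcs.std(ddof=1) / np.sqrt(tcs.size)) if tcs.size > 1 else 0.0
                summ.r2_mean = float(np.mean(
                    [f.r2 for (m, _), f in fits.items() if m == mat]))
        if reflectance and mat in reflectance:
            summ.reflectance = float(reflectance[mat])
        out.append(summ)
    return out
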