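"""Trend and association statistics for annual decay rate maps.

Provides the Mann-Kendall monotone-trend test with the five-level
significance classing used for mapping (increasing/decreasing at p < 0.05
and 0.05 <= p < 0.1, else none), reduced major axis (RMA) regression for
comparing two error-bearing measurements (e.g. the index derived from two
platforms), and Pearson/Spearman cross-correlation tables across gridded
variables.

Sign convention: because dense vegetation lowers the thermal decay rate,
an *increasing* trend class in the decay rate is interpreted as a
*decreasing* trend in vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rasters import GridSpec, RasterStack

__all__ = [
    "MKResult",
    "TrendClass",
    "TrendClassRaster",
    "RMAFit",
    "CorrelationTable",
    "mann_kendall",
    "classify_trend",
    "trend_map",
    "rma_regression",
    "correlation_table",
    "TREND_CLASS_CODES",
]

#: Integer codes used when a trend-class raster is written to file.
TREND_CLASS_CODES = {
    "decreasing_p05": -2,
    "decreasing_p10": -1,
    "none": 0,
    "increasing_p10": 1,
    "increasing_p05": 2,
}
TREND_CLASS_NODATA = -9  # insufficient data / masked

#: Default minimum valid years for a per-pixel trend (of a 15-year record).
DEFAULT_MIN_N = 10


@dataclass(frozen=True)
class MKResult:
    """Mann-Kendall test result.

    ``s`` is the signed count of concordant minus discordant time-ordered
    pairs; ``var_s`` its null variance with the tie correction; ``z`` the
    (optionally continuity-corrected) normal score; ``p`` the two-sided
    p-value; ``n`` the series length after missing removal.
    """

    s: int
    var_s: float
    z: float
    p: float
    n: int

    @property
    def valid(self) -> bool:
        return np.isfinite(self.p)


@dataclass(frozen=True)
class TrendClass:
    """One of the five mapped significance classes.

    For decay rate series, ``increasing_*`` means vegetation decrease.
    """

    label: str

    def __post_init__(self) -> None:
        if self.label not in TREND_CLASS_CODES:
            raise ValueError(f"unknown trend class {self.label!r}")

    @property
    def code(self) -> int:
        return TREND_CLASS_CODES[self.label]


@dataclass
class TrendClassRaster:
    """Per-pixel trend classes (integer codes; TREND_CLASS_NODATA = no data)."""

    codes: np.ndarray
    grid: GridSpec
    class_counts: dict


@dataclass(frozen=True)
class RMAFit:
    """Reduced major axis (geometric mean) regression fit."""

    slope: float
    intercept: float
    pearson_r: float
    n: int


@dataclass
class CorrelationTable:
    """Pairwise Pearson and Spearman matrices over jointly valid pixels."""

    variable_names: list
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    n_pixels: pd.DataFrame


def _tie_term(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t * (t - 1) * (2 * t + 5)))


def mann_kendall(
    series,
    min_n: int = DEFAULT_MIN_N,
    *,
    continuity: bool = True,
    tie_correction: bool = True,
) -> MKResult:
    """Mann-Kendall monotone trend test on an ordered series.

    Missing values (NaN) are removed; the remaining values keep their time
    order (gaps are allowed — the test uses ranks of time only through
    ordering).  S = sum_{i<j} sign(x_j - x_i); Var(S) =
    [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18 with the sum over tie groups;
    Z applies the +/-1 continuity correction (Z = 0 when S = 0); the
    p-value is two-sided from the normal approximation.

    Returns an all-NaN result (with ``n`` recorded) when fewer than
    ``min_n`` values remain.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < max(min_n, 2):
        return MKResult(0, float("nan"), float("nan"), float("nan"), n)
    diff_sign = np.sign(x[None, :] - x[:, None])
    s = int(np.sum(np.triu(diff_sign, k=1)))
    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_correction:
        var_s -= _tie_term(x) / 18.0
    if var_s <= 0:  # fully tied series
        return MKResult(s, 0.0, 0.0, 1.0, n)
    if s > 0:
        z = (s - (1 if continuity else 0)) / np.sqrt(var_s)
    elif s < 0:
        z = (s + (1 if continuity else 0)) / np.sqrt(var_s)
    else:
        z = 0.0
    p = float(2.0 * sps.norm.sf(abs(z)))
    return MKResult(s, float(var_s), float(z), min(p, 1.0), n)


def classify_trend(mk: MKResult, p05: float = 0.05, p10: float = 0.1) -> TrendClass:
    """Map (sign(S), p) to the five-level significance class."""
    if not mk.valid:
        raise ValueError("cannot classify an invalid (insufficient-n) result")
    if mk.p < p05:
        label = "increasing_p05" if mk.s > 0 else "decreasing_p05" if mk.s < 0 else "none"
    elif mk.p < p10:
        label = "increasing_p10" if mk.s > 0 else "decreasing_p10" if mk.s < 0 else "none"
    else:
        label = "none"
    return TrendClass(label)


def _mann_kendall_grid(values: np.ndarray, min_n: int, continuity: bool,
                       tie_correction: bool):
    """Vectorized MK over axis 0 of a (n_times, ...) array.

    Returns (s, var_s, z, p, n_valid) arrays; pixels with fewer than
    ``min_n`` finite values get NaN statistics.
    """
    v = np.asarray(values, dtype=float)
    nt = v.shape[0]
    finite = np.isfinite(v)
    n = finite.sum(axis=0)

    s = np.zeros(v.shape[1:])
    for i in range(nt - 1):
        d = v[i + 1:] - v[i]
        s += np.nansum(np.sign(d), axis=0)

    var_s = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_correction:
        # tie groups per pixel: sort (NaN last), accumulate t(t-1)(2t+5)
        # whenever an equal-value run ends
        vs = np.sort(v, axis=0)
        tie = np.zeros(v.shape[1:])
        run = np.ones(v.shape[1:])
        for i in range(1, nt + 1):
            if i < nt:
                same = (vs[i] == vs[i - 1]) & np.isfinite(vs[i]) & np.isfinite(vs[i - 1])
            else:
                same = np.zeros(v.shape[1:], dtype=bool)
            ending = ~same
            t = run
            tie = np.where(ending & (t > 1), tie + t * (t - 1) * (2 * t + 5), tie)
            run = np.where(same, run + 1, 1.0)
        var_s = var_s - tie / 18.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(var_s)
        corr = (1.0 if continuity else 0.0) * np.sign(s)
        z = np.where(s != 0, (s - corr) / sd, 0.0)
        z = np.where(var_s > 0, z, 0.0)
        p = 2.0 * sps.norm.sf(np.abs(z))
        p = np.where(var_s > 0, p, 1.0)
    bad = n < max(min_n, 2)
    for arr in (var_s, z, p):
        arr[bad] = np.nan
    return s, var_s, z, p, n


def trend_map(
    annual_maps: RasterStack,
    min_n: int = DEFAULT_MIN_N,
    *,
    continuity: bool = True,
    tie_correction: bool = True,
    p05: float = 0.05,
    p10: float = 0.1,
) -> TrendClassRaster:
    """Per-pixel Mann-Kendall trend classification of annual maps.

    Pixels with fewer than ``min_n`` valid years (including fully masked
    pixels) receive the nodata class code.
    """
    if annual_maps.values.shape[0] < 2:
        raise ValueError("trend analysis needs at least two annual layers")
    if annual_maps.values.shape[0] < min_n:
        raise ValueError(
            f"only {annual_maps.values.shape[0]} layers < min_n={min_n}"
        )
    s, var_s, z, p, n = _mann_kendall_grid(
        annual_maps.values, min_n, continuity, tie_correction
    )
    codes = np.full(s.shape, TREND_CLASS_NODATA, dtype=int)
    ok = np.isfinite(p)
    sig05 = ok & (p < p05)
    sig10 = ok & (p >= p05) & (p < p10)
    codes[ok] = TREND_CLASS_CODES["none"]
    codes[sig05 & (s > 0)] = TREND_CLASS_CODES["increasing_p05"]
    codes[sig05 & (s < 0)] = TREND_CLASS_CODES["decreasing_p05"]
    codes[sig10 & (s > 0)] = TREND_CLASS_CODES["increasing_p10"]
    codes[sig10 & (s < 0)] = TREND_CLASS_CODES["decreasing_p10"]
    counts = {label: int(np.count_nonzero(codes == code))
              for label, code in TREND_CLASS_CODES.items()}
    counts["nodata"] = int(np.count_nonzero(codes == TREND_CLASS_NODATA))
    return TrendClassRaster(codes, annual_maps.grid, counts)


def rma_regression(x, y) -> RMAFit:
    """Reduced major axis regression of y on x.

    slope = sign(r) * sd(y) / sd(x); intercept = mean(y) - slope * mean(x).
    Symmetric under axis exchange (slopes reciprocal).  Pairs with any NaN
    are dropped; at least 3 pairs and nonzero variance in both variables
    required.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("RMA needs at least 3 paired finite values")
    sx = np.std(x, ddof=1)
    sy = np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("RMA undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return RMAFit(float(slope), intercept, r, int(x.size))


def correlation_table(
    variables: Mapping[str, np.ndarray],
    mask: np.ndarray | None = None,
    min_pixels: int = 3,
) -> CorrelationTable:
    """Pairwise Pearson and Spearman correlations across gridded variables.

    All variables must share one grid shape.  ``mask`` (boolean, True =
    keep) restricts the analysis, e.g. to pixels above the 100 mm yr^-1
    precipitation threshold.  Each pair uses its jointly finite pixels
    (pairwise-complete deletion); pairs with fewer than ``min_pixels`` get
    NaN.  Latitude-like variables should be passed as absolute values by
    the caller when the association of interest is with distance from the
    equator.
    """
    names = list(variables)
    if len(names) < 2:
        raise ValueError("need at least two variables")
    shape = np.asarray(variables[names[0]]).shape
    flat = {}
    for name in names:
        arr = np.asarray(variables[name], dtype=float)
        if arr.shape != shape:
            raise ValueError(f"{name}: shape {arr.shape} != {shape}")
        v = arr.ravel()
        if mask is not None:
            v = np.where(np.asarray(mask, dtype=bool).ravel(), v, np.nan)
        flat[name] = v

    k = len(names)
    pear = np.full((k, k), np.nan)
    spear = np.full((k, k), np.nan)
    npix = np.zeros((k, k), dtype=int)
    for i in range(k):
        pear[i, i] = spear[i, i] = 1.0
        npix[i, i] = int(np.isfinite(flat[names[i]]).sum())
        for j in range(i + 1, k):
            xi, xj = flat[names[i]], flat[names[j]]
            ok = np.isfinite(xi) & np.isfinite(xj)
            npix[i, j] = npix[j, i] = int(ok.sum())
            if ok.sum() < min_pixels:
                continue
            pr = sps.pearsonr(xi[ok], xj[ok]).statistic
            sr = sps.spearmanr(xi[ok], xj[ok]).statistic
            pear[i, j] = pear[j, i] = pr
            spear[i, j] = spear[j, i] = sr
    return CorrelationTable(
        names,
        pearson=pd.DataFrame(pear, index=names, columns=names),
        spearman=pd.DataFrame(spear, index=names, columns=names),
        n_pixels=pd.DataFrame(npix, index=names, columns=names),
    )
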