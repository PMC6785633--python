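"""Periodicity detection engine for short, evenly sampled time courses.

The engine mirrors the two-method meta-analysis design used for circadian
screens: a nonparametric rank test (JTK_CYCLE style) and a Lomb-Scargle
periodogram are run per replicate series, their p-values merged by Fisher's
chi-square combination (2k degrees of freedom for k p-values), and the
replicate-level meta p-values merged again across replicates. Fitted
periods are averaged between the two methods; amplitude and phase come from
a post-hoc least-squares cosine fit at the mean period.

JTK_CYCLE here computes Kendall's S between the observed series and cosine
reference patterns over a grid of (period, lag) pairs, with an *exact* null
distribution of S obtained by the Harding convolution of Mann-Whitney count
distributions over the reference tie groups (feasible for n <= 12). The
minimum p over all patterns is reported uncorrected, which is the published
JTK_CYCLE convention and makes the test anticonservative by construction;
downstream significance thresholds account for this (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy import signal, stats

PERIOD_GROUPS = (12.0, 18.0, 24.0, 30.0)
PERIOD_GROUP_HALFWIDTH = 3.0
PHASE_GROUPS = {"0": 0.0, "pi/2": 0.5 * math.pi, "pi": math.pi, "-pi/2": 1.5 * math.pi}

_TINY_P = 1e-300


@dataclass(frozen=True)
class JtkResult:
    period: float | None
    lag: float | None
    p: float


@dataclass(frozen=True)
class LombResult:
    period: float | None
    p: float
    peak_power: float
    frequencies: np.ndarray
    power: np.ndarray


@dataclass(frozen=True)
class RhythmResult:
    """Meta-fit of one series: per-method and combined evidence of rhythm."""

    series_id: str
    p_jtk: float
    p_ls: float
    p_combined: float
    period_jtk: float
    period_ls: float
    period_mean: float
    phase_h: float
    amplitude: float
    base: float
    period_group: int | None
    phase_group: str | None


# -- JTK_CYCLE exact null --------------------------------------------------


def _mw_counts(m: int, n: int) -> list[int]:
    """Counts of the Mann-Whitney U statistic for group sizes (m, n).

    Coefficients of the Gaussian binomial [m+n choose n]_q, computed by
    exact polynomial multiplication/division with Python integers.
    """
    if m == 0 or n == 0:
        return [1]
    c = [1]
    deg = 0
    for j in range(1, n + 1):
        a = m + j
        nd = deg + a
        new = [0] * (nd + 1)
        for i in range(nd + 1):
            v = c[i] if i <= deg else 0
            if a <= i and i - a <= deg:
                v -= c[i - a]
            new[i] = v
        dd = nd - j
        div = [0] * (dd + 1)
        for i in range(dd + 1):
            v = new[i]
            if i >= j:
                v += div[i - j]
            div[i] = v
        c, deg = div, dd
    return c


@lru_cache(maxsize=None)
def _jt_null(group_sizes: tuple[int, ...]) -> tuple[int, tuple[float, ...]]:
    """Exact null of the Jonckheere-Terpstra statistic for tie-group sizes.

    Returns (max_JT, probabilities over JT = 0..max_JT). Kendall's S for a
    series against a tied reference pattern is S = 2*JT - max_JT.
    """
    counts = np.array([1.0])
    m = group_sizes[0]
    for g in group_sizes[1:]:
        u = np.array(_mw_counts(m, g), dtype=float)
        counts = np.convolve(counts, u)
        m += g
    probs = counts / counts.sum()
    return len(probs) - 1, tuple(probs)


def _kendall_s(y: np.ndarray, group_sizes: Sequence[int]) -> int:
    """Kendall S between y (ordered by ascending reference value) and the
    reference tie-group pattern: sum of sign(y_j - y_i) over cross-group
    pairs with group(i) < group(j)."""
    s = 0
    bounds = np.cumsum([0, *group_sizes])
    for gi in range(len(group_sizes)):
        for gj in range(gi + 1, len(group_sizes)):
            yi = y[bounds[gi]:bounds[gi + 1]]
            yj = y[bounds[gj]:bounds[gj + 1]]
            diff = yj[:, None] - yi[None, :]
            s += int(np.sign(diff).sum())
    return s


def _tie_corrected_p(s: int, n: int, t_sizes: Sequence[int], u_sizes: Sequence[int]) -> float:
    """Normal approximation for P(|S| >= |s|) with ties on both variables."""
    t = np.asarray(t_sizes, dtype=float)
    u = np.asarray(u_sizes, dtype=float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((t * (t - 1) * (2 * t + 5)).sum())
    vu = float((u * (u - 1) * (2 * u + 5)).sum())
    var = (v0 - vt - vu) / 18.0
    if n > 2:
        var += (
            float((t * (t - 1) * (t - 2)).sum())
            * float((u * (u - 1) * (u - 2)).sum())
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var += float((t * (t - 1)).sum()) * float((u * (u - 1)).sum()) / (2.0 * n * (n - 1))
    if var <= 0:
        return 1.0
    z = max(abs(s) - 1, 0) / math.sqrt(var)  # continuity correction
    return min(1.0, 2.0 * stats.norm.sf(z))


def _pattern_p(y: np.ndarray, ref: np.ndarray) -> float:
    """Two-sided p-value of Kendall concordance between y and a reference."""
    order = np.argsort(ref, kind="stable")
    y_ord = y[order]
    ref_ord = ref[order]
    group_sizes: list[int] = []
    run = 1
    for a, b in zip(ref_ord, ref_ord[1:]):
        if b == a:
            run += 1
        else:
            group_sizes.append(run)
            run = 1
    group_sizes.append(run)
    if len(group_sizes) == 1:
        return 1.0
    s = _kendall_s(y_ord, group_sizes)
    if len(np.unique(y)) == len(y):
        max_jt, probs = _jt_null(tuple(group_sizes))
        jt_vals = 2 * np.arange(max_jt + 1) - max_jt  # S values
        mask = np.abs(jt_vals) >= abs(s)
        return float(np.asarray(probs)[mask].sum())
    uniq, counts = np.unique(y, return_counts=True)
    return _tie_corrected_p(s, len(y), group_sizes, counts.tolist())


def jtk_cycle(
    values: Sequence[float],
    times: Sequence[float],
    periods: Sequence[float] | None = None,
) -> JtkResult:
    """JTK_CYCLE rank test over a grid of candidate (period, lag) pairs.

    ``periods`` defaults to 2*dt .. n*dt (e.g. 12..36 h for 6 samples every
    6 h). Lags scan the full period in steps of the grid spacing; the
    reference cosine peaks at t = lag, so the best lag estimates the phase.
    Returns the minimum p over all patterns (JTK_CYCLE convention).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.ndim != 1 or y.size != t.size:
        raise ValueError("values and times must be 1-D and equally long")
    if y.size < 4:
        raise ValueError("need at least 4 points for rhythm detection")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    diffs = np.diff(t)
    if diffs.size == 0 or not np.allclose(diffs, diffs[0]):
        raise ValueError("JTK requires an evenly spaced grid")
    dt = float(diffs[0])
    if periods is None:
        periods = [k * dt for k in range(2, y.size + 1)]
    if np.ptp(y) == 0:
        return JtkResult(None, None, 1.0)
    best_p = 1.0
    best_period: float | None = None
    best_lag: float | None = None
    for period in periods:
        n_lags = max(1, int(round(period / dt)))
        for lag in (k * dt for k in range(n_lags)):
            if lag >= period:
                continue
            ref = np.round(np.cos(2.0 * np.pi * (t - lag) / period), 9)
            if np.ptp(ref) == 0:
                continue
            p = _pattern_p(y, ref)
            if p < best_p:
                best_p, best_period, best_lag = p, float(period), float(lag)
    return JtkResult(best_period, best_lag, best_p)


# -- Lomb-Scargle ----------------------------------------------------------


def lomb_scargle(
    values: Sequence[float],
    times: Sequence[float],
    period_range: tuple[float, float] = (12.0, 48.0),
    oversample: float = 10.0,
    tail: str = "beta",
    n_effective: str = "scanned",
) -> LombResult:
    """Classical normalized Lomb-Scargle periodogram with peak significance.

    The periodogram is normalized by the sample variance (ddof=1). The peak
    p-value is 1 - (1 - p1)^M (Horne-Baliunas style) where p1 is the
    single-frequency tail: by default the finite-sample beta form
    p1 = (1 - 2z/(n-1))^((n-3)/2), exact for Gaussian noise at this
    normalization; ``tail="exponential"`` selects the large-n limit e^(-z).
    M defaults to the raw count of scanned frequencies ("scanned"), which
    is deliberately conservative: with very short series the periodogram
    peak sits close to its ceiling (n-1)/2, where the beta tail is so steep
    that the nominally correct independent-frequency count
    ("independent", span*(f_max - f_min) + 1) becomes anticonservative.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 points for rhythm detection")
    if tail not in ("beta", "exponential"):
        raise ValueError(f"unknown tail {tail!r}")
    if n_effective not in ("independent", "scanned"):
        raise ValueError(f"unknown n_effective {n_effective!r}")
    lo, hi = min(period_range), max(period_range)
    span = float(t.max() - t.min())
    df = 1.0 / (oversample * span)
    freqs = np.arange(1.0 / hi, 1.0 / lo + 0.5 * df, df)
    n = y.size
    var = float(y.var(ddof=1))
    if var == 0.0 or np.ptp(y) == 0.0:
        return LombResult(None, 1.0, 0.0, freqs, np.zeros_like(freqs))
    power = signal.lombscargle(t, y - y.mean(), 2.0 * np.pi * freqs) / var
    i = int(np.argmax(power))
    z = float(power[i])
    if tail == "beta":
        p1 = max(0.0, 1.0 - 2.0 * z / (n - 1)) ** ((n - 3) / 2.0)
    else:
        p1 = math.exp(-z)
    if n_effective == "independent":
        m = max(1, round(span * (1.0 / lo - 1.0 / hi))) + 1
    else:
        m = len(freqs)
    if p1 <= 0.0:
        p = 0.0
    else:
        p = -math.expm1(m * math.log1p(-min(p1, 1.0)))
    p = min(1.0, max(p, _TINY_P))
    return LombResult(1.0 / float(freqs[i]), p, z, freqs, power)


# -- Fisher combination ----------------------------------------------------


def fisher_combine(p_values: Iterable[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df under H0."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(ps > 1.0) or np.any(ps < 0.0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0.0):
        warnings.warn("p-value of 0 clamped to the smallest positive value", stacklevel=2)
        ps = np.maximum(ps, _TINY_P)
    x = -2.0 * float(np.log(ps).sum())
    return float(stats.chi2.sf(x, 2 * ps.size))


# -- cosine fit and grouping ----------------------------------------------


def cosine_fit(values: Sequence[float], times: Sequence[float], period: float) -> tuple[float, float, float]:
    """Least-squares fit of base + A*cos(2*pi*(t - phase)/period).

    Returns (base, amplitude, phase_h) with phase_h in [0, period), the time
    of the first maximum. Phase is NaN for a zero-amplitude fit.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    w = 2.0 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    base, a, b = (float(c) for c in coef)
    amplitude = math.hypot(a, b)
    if amplitude < 1e-12:
        return base, 0.0, math.nan
    phase_h = (math.atan2(b, a) / w) % period
    return base, amplitude, phase_h


def assign_period_group(
    period_mean: float,
    groups: Sequence[float] = PERIOD_GROUPS,
    halfwidth: float = PERIOD_GROUP_HALFWIDTH,
) -> int | None:
    """Snap a fitted period to 12/18/24/30 h (each +- 3 h), else None.

    Values within two windows go to the nearer center; exact midpoints go to
    the lower center.
    """
    if period_mean is None or not np.isfinite(period_mean):
        return None
    candidates = [g for g in sorted(groups) if abs(period_mean - g) <= halfwidth]
    if not candidates:
        return None
    best = min(candidates, key=lambda g: (abs(period_mean - g), g))
    return int(best)


def assign_phase_group(phase_h: float, period_h: float, twelve_h: bool = False) -> str | None:
    """Snap phase to the nearest quadrant of the cycle: 0, pi/2, pi, -pi/2.

    For the 12 h period group only {0, pi} are resolvable at 6 h sampling,
    so quadrature labels are suppressed (``twelve_h=True``).
    """
    if phase_h is None or not np.isfinite(phase_h) or not np.isfinite(period_h) or period_h <= 0:
        return None
    phi = (2.0 * math.pi * phase_h / period_h) % (2.0 * math.pi)
    allowed = {"0": 0.0, "pi": math.pi} if twelve_h else PHASE_GROUPS
    def circ_dist(a: float, b: float) -> float:
        d = abs(a - b) % (2.0 * math.pi)
        return min(d, 2.0 * math.pi - d)
    return min(allowed, key=lambda k: (circ_dist(phi, allowed[k]), allowed[k]))


def zscore_normalize(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sd 1 (sample sd); constant series map to 0."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = y.std(ddof=1)
    if sd == 0:
        return np.zeros_like(y)
    return (y - y.mean()) / sd


# -- meta fit --------------------------------------------------------------


def meta_fit(
    values: Sequence[float] | np.ndarray,
    times: Sequence[float],
    *,
    series_id: str = "",
    periods: Sequence[float] | None = None,
    ls_period_range: tuple[float, float] = (12.0, 48.0),
    ls_oversample: float = 10.0,
    ls_tail: str = "beta",
    ls_n_effective: str = "scanned",
    strategy: str = "replicates",
) -> RhythmResult:
    """Run JTK and Lomb-Scargle per replicate and combine the evidence.

    ``values`` is (n_replicates, n_times) or a single 1-D series. With the
    default ``strategy="replicates"``, each replicate's {p_jtk, p_ls} pair
    is Fisher-combined (df 4) and the per-replicate meta p-values are then
    combined across replicates (df 2k, k = number of replicates);
    ``strategy="flat"`` combines all 2k p-values in a single Fisher test.
    """
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.asarray(times, dtype=float)
    if arr.shape[1] != t.size:
        raise ValueError("each replicate series must match the time grid")
    if strategy not in ("replicates", "flat"):
        raise ValueError(f"unknown strategy {strategy!r}")

    jtk_fits = [jtk_cycle(row, t, periods=periods) for row in arr]
    ls_fits = [
        lomb_scargle(
            row, t, period_range=ls_period_range, oversample=ls_oversample,
            tail=ls_tail, n_effective=ls_n_effective,
        )
        for row in arr
    ]
    jtk_ps = [f.p for f in jtk_fits]
    ls_ps = [f.p for f in ls_fits]
    if strategy == "replicates":
        rep_meta = [fisher_combine([pj, pl]) for pj, pl in zip(jtk_ps, ls_ps)]
        p_combined = rep_meta[0] if len(rep_meta) == 1 else fisher_combine(rep_meta)
    else:
        p_combined = fisher_combine(jtk_ps + ls_ps)
    p_jtk = jtk_ps[0] if len(jtk_ps) == 1 else fisher_combine(jtk_ps)
    p_ls = ls_ps[0] if len(ls_ps) == 1 else fisher_combine(ls_ps)

    jtk_periods = [f.period for f in jtk_fits if f.period is not None]
    ls_periods = [f.period for f in ls_fits if f.period is not None]
    period_jtk = float(np.mean(jtk_periods)) if jtk_periods else math.nan
    period_ls = float(np.mean(ls_periods)) if ls_periods else math.nan
    both = [p for p in (period_jtk, period_ls) if np.isfinite(p)]
    period_mean = float(np.mean(both)) if both else math.nan

    mean_series = arr.mean(axis=0)
    if np.isfinite(period_mean) and np.ptp(mean_series) > 0:
        base, amplitude, phase_h = cosine_fit(mean_series, t, period_mean)
    else:
        base, amplitude, phase_h = float(mean_series.mean()), 0.0, math.nan

    period_group = assign_period_group(period_mean)
    phase_group = assign_phase_group(phase_h, period_mean, twelve_h=(period_group == 12))
    return RhythmResult(
        series_id=series_id,
        p_jtk=float(p_jtk),
        p_ls=float(p_ls),
        p_combined=float(p_combined),
        period_jtk=period_jtk,
        period_ls=period_ls,
        period_mean=period_mean,
        phase_h=phase_h if phase_h is not None else math.nan,
        amplitude=amplitude,
        base=base,
        period_group=period_group,
        phase_group=phase_group,
    )
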