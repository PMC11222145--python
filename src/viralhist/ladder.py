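"""Quantification of MNase digestion ladders from fragment-size traces.

A nuclease-protection ladder appears in a Bioanalyzer-style
electropherogram as a series of peaks at sizes P, P(1+f), P(1+2f), …:
``P`` is the primary protected fragment (one nucleosomal unit) and the
step fraction ``f`` measures how much each higher-order band adds,
relative to the primary.  Two estimators are provided:

* :func:`detect_peaks` + :func:`summarize_ladder` — non-parametric local
  maxima after smoothing, adequate when bands are well separated;
* :func:`fit_ladder` — a Gaussian-comb least-squares fit that remains
  accurate when neighbouring bands blur into shoulders (small ``P·f``
  relative to the band width).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.optimize import least_squares, nnls
from scipy.signal import find_peaks


@dataclass(frozen=True)
class Electropherogram:
    """A 1-D fragment-size trace (sizes in bp, intensities ≥ 0)."""

    sizes: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if s.shape != y.shape:
            raise ValueError("sizes and intensities differ in length")
        if not np.all(np.diff(s) > 0):
            raise ValueError("sizes must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "sizes", s)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class LadderSummary:
    """Primary fragment size and higher-order step statistics."""

    peak_sizes: tuple[float, ...]
    primary_bp: float
    steps_bp: tuple[float, ...]
    step_ratio_pct: float | None  # None when <2 peaks


@dataclass(frozen=True)
class LadderFit:
    """Parametric Gaussian-comb estimate of a ladder."""

    primary_bp: float
    step_bp: float
    step_fraction: float
    peak_sd: float
    heights: tuple[float, ...]
    rss: float


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def subtract_baseline(eg: Electropherogram, window: int = 101) -> Electropherogram:
    """Rolling-minimum baseline subtraction (optional preprocessing)."""
    base = uniform_filter1d(minimum_filter1d(eg.intensities, window), window)
    return Electropherogram(eg.sizes, np.maximum(eg.intensities - base, 0.0),
                            eg.label)


def detect_peaks(eg: Electropherogram, min_prominence_frac: float = 0.05,
                 smooth_window: int = 5) -> list[float]:
    """Local maxima of the smoothed trace, filtered by relative prominence.

    A peak is kept if its prominence reaches ``min_prominence_frac`` of
    the maximum smoothed intensity.  Returns peak sizes in ascending bp;
    a flat trace yields an empty list.
    """
    if eg.sizes.size < 3:
        raise ValueError("trace needs at least 3 points")
    y = uniform_filter1d(eg.intensities, max(1, smooth_window), mode="nearest")
    top = float(np.max(y))
    if top <= 0 or np.ptp(y) == 0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence_frac * top)
    return [float(s) for s in eg.sizes[idx]]


def peak_heights(eg: Electropherogram, peaks: Sequence[float],
                 smooth_window: int = 5) -> list[float]:
    """Smoothed intensity at each peak size."""
    y = uniform_filter1d(eg.intensities, max(1, smooth_window), mode="nearest")
    return [float(y[np.argmin(np.abs(eg.sizes - p))]) for p in peaks]


# ---------------------------------------------------------------------------
# summarisation
# ---------------------------------------------------------------------------

def summarize_ladder(peaks: Sequence[float],
                     primary: Literal["smallest", "most_intense"] = "smallest",
                     heights: Sequence[float] | None = None) -> LadderSummary:
    """Steps between successive peaks and the step-to-primary ratio.

    The primary fragment defaults to the smallest prominent peak (the
    mono-nucleosome band); ``most_intense`` requires ``heights``.  With a
    single peak the steps are empty and the ratio undefined.
    """
    if not peaks:
        raise ValueError("no peaks to summarise")
    ordered = sorted(float(p) for p in peaks)
    if primary == "smallest":
        primary_bp = ordered[0]
    elif primary == "most_intense":
        if heights is None or len(heights) != len(peaks):
            raise ValueError("primary='most_intense' requires matching heights")
        primary_bp = float(peaks[int(np.argmax(heights))])
    else:
        raise ValueError(f"unknown primary rule {primary!r}")
    steps = tuple(float(b - a) for a, b in zip(ordered, ordered[1:]))
    ratio = float(np.mean(steps) / primary_bp * 100.0) if steps else None
    return LadderSummary(tuple(ordered), primary_bp, steps, ratio)


def step_ratio_across_samples(summaries: Sequence[LadderSummary]
                              ) -> dict[str, float]:
    """Mean step-to-primary percentage, by both averaging orders.

    ``per_sample_mean`` averages each sample's ratio first (samples
    weighted equally); ``pooled`` pools all steps and all primaries.
    """
    with_steps = [s for s in summaries if s.step_ratio_pct is not None]
    if not with_steps:
        raise ValueError("no multi-peak ladders to average")
    per_sample = float(np.mean([s.step_ratio_pct for s in with_steps]))
    all_steps = np.concatenate([s.steps_bp for s in with_steps])
    mean_primary = float(np.mean([s.primary_bp for s in with_steps]))
    pooled = float(np.mean(all_steps) / mean_primary * 100.0)
    return {"per_sample_mean": per_sample, "pooled": pooled}


# ---------------------------------------------------------------------------
# parametric comb fit
# ---------------------------------------------------------------------------

def _comb_design(sizes: np.ndarray, primary: float, step: float,
                 sd: float, n_comp: int) -> np.ndarray:
    centers = primary + step * np.arange(n_comp)
    cols = np.exp(-0.5 * ((sizes[:, None] - centers[None, :]) / sd) ** 2)
    return np.column_stack([cols, np.ones_like(sizes)])


def _comb_rss(sizes: np.ndarray, y: np.ndarray, primary: float, step: float,
              sd: float, n_comp: int) -> tuple[float, np.ndarray]:
    X = _comb_design(sizes, primary, step, sd, n_comp)
    coef, _ = nnls(X, y)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_ladder(eg: Electropherogram, max_orders: int = 4,
               sd_grid: Sequence[float] = (3.0, 5.0, 8.0),
               step_range: tuple[float, float] = (8.0, 170.0),
               smooth_window: int = 5) -> LadderFit:
    """Least-squares Gaussian-comb fit of a digestion ladder.

    Peak centers are constrained to the arithmetic ladder
    P, P+s, …, P+(k−1)s with a shared band width; heights (non-negative)
    and a constant offset are profiled out by non-negative least squares
    on a coarse (P, s, sd) grid, then the best candidates are refined by
    unconstrained continuous optimisation.  Robust to bands that have
    merged into shoulders, where simple peak picking under-counts.
    """
    sizes, y = eg.sizes, eg.intensities
    if sizes.size < 10:
        raise ValueError("trace too short for a comb fit")
    ys = uniform_filter1d(y, max(3, smooth_window), mode="nearest")
    m = float(sizes[int(np.argmax(ys))])  # tallest band: near P (heights decay)

    lo_s, hi_s = step_range
    hi_s = min(hi_s, float(sizes[-1] - sizes[0]))

    # candidate (P, s) pairs: P stays near the tallest band; a leading
    # zero-height tooth is trimmed afterwards, so P need not be exact
    candidates: list[tuple[float, float, float, float]] = []
    peaks = detect_peaks(eg, min_prominence_frac=0.2, smooth_window=9)
    if len(peaks) >= 2:
        diffs = np.diff(peaks)
        s_hat = float(np.median(diffs))
        if lo_s <= s_hat <= hi_s:
            for sd in sd_grid:
                rss, _ = _comb_rss(sizes, y, float(peaks[0]), s_hat, sd,
                                   max_orders)
                candidates.append((rss, float(peaks[0]), s_hat, sd))
    for step in np.arange(lo_s, hi_s + 1e-9, 2.5):
        p_lo = max(float(sizes[0]) + 1.0, m - 6.0)
        p_hi = min(m + 3.0, float(sizes[-1]) - 1.0)
        for primary in np.arange(p_lo, p_hi + 1e-9, 1.5):
            for sd in (4.0, 6.0):
                rss, _ = _comb_rss(sizes, y, primary, step, sd, max_orders)
                candidates.append((rss, primary, step, sd))
    candidates.sort(key=lambda c: c[0])

    best = None
    for rss0, p0, s0, sd0 in candidates[:3]:
        x0 = np.array([p0, s0, sd0])

        def objective(x):
            rss, _ = _comb_rss(sizes, y, x[0], x[1], x[2], max_orders)
            return np.sqrt(max(rss, 0.0))

        res = least_squares(
            objective, x0,
            bounds=([sizes[0], 1.0, 0.5], [sizes[-1], hi_s + 10.0, 30.0]),
            diff_step=1e-3, xtol=1e-10,
        )
        rss, coef = _comb_rss(sizes, y, *res.x, max_orders)
        if best is None or rss < best[0]:
            best = (rss, res.x, coef)

    rss, (primary, step, sd), coef = best
    heights = list(float(h) for h in coef[:-1])
    # trim leading/trailing near-empty comb teeth: the comb is identified
    # only up to integer shifts when edge teeth carry no intensity
    floor = 0.05 * max(heights)
    lead = 0
    while lead < len(heights) - 1 and heights[lead] <= floor:
        lead += 1
    primary = primary + lead * step
    heights = heights[lead:]
    while len(heights) > 1 and heights[-1] <= floor:
        heights.pop()
    return LadderFit(
        primary_bp=float(primary),
        step_bp=float(step),
        step_fraction=float(step / primary),
        peak_sd=float(sd),
        heights=tuple(heights),
        rss=rss,
    )
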