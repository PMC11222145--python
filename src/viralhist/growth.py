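"""Gompertz growth-curve fitting and condition comparison.

Blank-subtracted OD600 curves are fit with the modified Gompertz model

    y(t) = A · exp(−exp((µ·e/A)·(λ − t) + 1))

whose parameters carry their standard growth-curve meanings: ``A`` is the
curve maximum (maximum growth), ``µ`` the maximum slope (maximum growth
rate, attained at the inflection point t = λ + A/(µ·e)), and ``λ`` the
lag time — the intercept of the inflection tangent with y = 0.  Fitted
parameters are compared across conditions with Tukey HSD tests and a
Bonferroni factor across the three parameters, summarised as a compact
letter display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.stats.multicomp import pairwise_tukeyhsd

_E = float(np.e)

PARAMETERS = ("A", "mu", "lam")


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate's plate-reader time course.

    ``blank`` is the OD600 of uninoculated media, per time point or as a
    scalar, subtracted point-wise before fitting.
    """

    strain: str
    condition: str
    replicate: int
    times: np.ndarray
    od: np.ndarray
    blank: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if t.shape != y.shape:
            raise ValueError("times and od differ in length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)

    def blank_subtracted(self) -> np.ndarray:
        return self.od - np.asarray(self.blank, dtype=float)


@dataclass(frozen=True)
class GompertzFit:
    strain: str
    condition: str
    replicate: int
    A: float
    mu: float
    lam: float
    rss: float
    converged: bool
    n_iter: int


@dataclass(frozen=True)
class ConditionComparison:
    parameter: str
    table: pd.DataFrame        # group1, group2, meandiff, p_tukey, p_adjusted
    letters: dict[str, str]    # compact letter display
    alpha: float


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def gompertz_model(t, A: float, mu: float, lam: float):
    """Modified Gompertz curve value at time ``t`` (hours)."""
    if A <= 0:
        raise ValueError("A must be positive")
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp((mu * _E / A) * (lam - t) + 1.0))


def _residuals(params, t, y):
    A, mu, lam = params
    return A * np.exp(-np.exp((mu * _E / A) * (lam - t) + 1.0)) - y


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Data-driven starting values: A from the maximum, µ from the
    steepest finite-difference slope, λ from the tangent at that point."""
    A0 = float(np.max(y))
    slopes = np.diff(y) / np.diff(t)
    i = int(np.argmax(slopes))
    mu0 = max(float(slopes[i]), 1e-6)
    t_mid = 0.5 * (t[i] + t[i + 1])
    y_mid = 0.5 * (y[i] + y[i + 1])
    lam0 = t_mid - y_mid / mu0
    return np.array([max(A0, 1e-6), mu0, lam0])


def fit_gompertz(curve: GrowthCurve, max_iter: int = 10_000,
                 tol: float = 1e-5, n_restarts: int = 3,
                 seed: int = 0) -> GompertzFit:
    """Nonlinear least-squares fit of the Gompertz model.

    The blank is subtracted point-wise first.  Non-convergence (including
    degenerate inputs such as all-zero or monotonically decreasing
    signals) is reported through ``converged=False``, never an exception.
    On failure the fit is retried from jittered starting values
    (``n_restarts`` seeded attempts).
    """
    t = curve.times
    y = curve.blank_subtracted()
    failed = GompertzFit(curve.strain, curve.condition, curve.replicate,
                         A=float("nan"), mu=float("nan"), lam=float("nan"),
                         rss=float("nan"), converged=False, n_iter=0)
    if t.size < 5:
        return failed
    if np.max(y) <= 1e-9 or np.all(np.diff(y) <= 0):
        return failed

    x0 = _initial_guess(t, y)
    rng = np.random.default_rng(seed)
    lower = np.array([1e-9, 1e-9, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf])
    best = None
    for attempt in range(1 + n_restarts):
        start = x0 if attempt == 0 else np.maximum(
            x0 * rng.lognormal(0.0, 0.3, size=3), lower + 1e-9)
        try:
            res = least_squares(
                _residuals, np.clip(start, lower + 1e-9, None),
                args=(t, y), bounds=(lower, upper),
                ftol=tol, xtol=1e-12, max_nfev=max_iter,
            )
        except Exception:
            continue
        if res.success:
            best = res
            break
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return failed
    A, mu, lam = (float(v) for v in best.x)
    rss = float(2.0 * best.cost)
    converged = bool(best.success) and np.isfinite(rss) and A > 0 and mu > 0
    return GompertzFit(curve.strain, curve.condition, curve.replicate,
                       A=A, mu=mu, lam=lam, rss=rss,
                       converged=converged, n_iter=int(best.nfev))


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def _compact_letter_display(groups: Sequence[str],
                            significant: set[tuple[str, str]],
                            means: Mapping[str, float]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; letters are
    assigned scanning groups by descending mean.
    """
    ordered = sorted(groups, key=lambda g: -means[g])
    columns: list[set[str]] = [set(ordered)]
    for a, b in sorted(significant):
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
            # absorb columns that became subsets of another
            columns = [c for c in columns
                       if not any(c < other for other in columns)]
    # deduplicate while keeping deterministic order
    unique: list[set[str]] = []
    for c in columns:
        if c and c not in unique:
            unique.append(c)
    unique.sort(key=lambda c: min(ordered.index(g) for g in c))
    letters = {g: "" for g in ordered}
    for sym, col in zip("abcdefghijklmnopqrstuvwxyz", unique):
        for g in ordered:
            if g in col:
                letters[g] += sym
    for g in ordered:  # isolated groups (all pairs significant)
        if not letters[g]:
            letters[g] = chr(ord("a") + len(unique))
    return letters


def compare_conditions(fits: Mapping[str, Sequence[GompertzFit]],
                       parameter: Literal["A", "mu", "lam"],
                       alpha: float = 0.01,
                       bonferroni_m: int = 3) -> ConditionComparison:
    """Tukey HSD across groups on one fitted parameter.

    Only converged fits enter; groups with fewer than two converged
    replicates are excluded with a warning.  Tukey-adjusted P values are
    further multiplied by ``bonferroni_m`` (the number of parameters
    tested, 3 by default) and capped at 1.  Letters come from the compact
    letter display at ``alpha`` on the adjusted P values.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"parameter must be one of {PARAMETERS}")
    usable: dict[str, np.ndarray] = {}
    for label, group in fits.items():
        vals = np.array([getattr(f, parameter) for f in group if f.converged])
        if vals.size < 2:
            warnings.warn(
                f"group {label!r} has <2 converged fits and is excluded")
            continue
        usable[label] = vals
    if not usable:
        raise ValueError("no group has ≥2 converged fits")
    means = {g: float(np.mean(v)) for g, v in usable.items()}
    if len(usable) == 1:
        (label,) = usable
        table = pd.DataFrame(columns=["group1", "group2", "meandiff",
                                      "p_tukey", "p_adjusted"])
        return ConditionComparison(parameter, table, {label: "a"}, alpha)

    values = np.concatenate(list(usable.values()))
    labels = np.concatenate([[g] * len(v) for g, v in usable.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    from itertools import combinations
    pairs = list(combinations([str(g) for g in tukey.groupsunique], 2))
    p_tukey = np.asarray(tukey.pvalues, dtype=float)
    p_adj = np.minimum(p_tukey * bonferroni_m, 1.0)
    table = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "meandiff": np.asarray(tukey.meandiffs, dtype=float),
        "p_tukey": p_tukey,
        "p_adjusted": p_adj,
    })
    significant = {
        tuple(sorted((r.group1, r.group2)))
        for r in table.itertuples() if r.p_adjusted < alpha
    }
    letters = _compact_letter_display(list(usable), significant, means)
    return ConditionComparison(parameter, table, letters, alpha)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

GROWTH_COLUMNS = ["strain", "condition", "replicate", "time_h", "od600",
                  "blank_od600"]


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """Read long-format plate-reader CSV into per-replicate curves."""
    df = pd.read_csv(path)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"growth CSV missing columns {missing}")
    curves = []
    for (strain, condition, rep), sub in df.groupby(
            ["strain", "condition", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        curves.append(GrowthCurve(
            strain=str(strain), condition=str(condition), replicate=int(rep),
            times=sub["time_h"].to_numpy(float),
            od=sub["od600"].to_numpy(float),
            blank=sub["blank_od600"].to_numpy(float),
        ))
    return curves


def fits_table(fits: Sequence[GompertzFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "strain": f.strain, "condition": f.condition, "replicate": f.replicate,
        "A": f.A, "mu": f.mu, "lam": f.lam, "rss": f.rss,
        "converged": f.converged, "n_iter": f.n_iter,
    } for f in fits])
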