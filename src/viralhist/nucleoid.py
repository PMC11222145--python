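"""Per-cell fluorescence transects: normalisation, averaging, KS comparison.

Each cell contributes one intensity transect along its long axis.  Cells
outside the 2–4 µm length window are excluded (size control), each
transect is normalised to its own maximum and resampled by linear
interpolation onto a fixed relative-position grid on [0, 1], and strains
are summarised by the per-grid-point mean ± standard error.

Strains are compared with a two-sample Kolmogorov–Smirnov test on the
pooled normalised intensity values (all cells × all grid points).
Because values within one cell are not independent, the default P value
comes from a cell-label permutation null, which is calibrated at the cell
level; the classical asymptotic P (computed as if all pooled values were
independent) is available with ``n_permutations=0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class NucleoidTransect:
    """One cell's intensity profile along the long axis."""

    cell_id: str
    strain: str
    cell_length: float  # µm
    positions: np.ndarray  # µm from one cell pole
    intensities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if p.shape != y.shape:
            raise ValueError("positions and intensities differ in length")
        if not np.all(np.diff(p) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class ProfileSummary:
    strain: str
    grid: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_cells: int


@dataclass(frozen=True)
class KSComparison:
    strain_a: str
    strain_b: str
    D: float
    p_raw: float
    p_adjusted: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# filtering / normalisation
# ---------------------------------------------------------------------------

def filter_by_length(cells: Iterable[NucleoidTransect], min_um: float = 2.0,
                     max_um: float = 4.0) -> list[NucleoidTransect]:
    """Keep cells whose length lies within [min_um, max_um]."""
    return [c for c in cells if min_um <= c.cell_length <= max_um]


def normalize_and_resample(cell: NucleoidTransect,
                           n_grid: int = 100) -> np.ndarray:
    """Max-normalised profile on a fixed relative-position grid.

    Intensities are divided by the cell's maximum; positions are mapped
    to [0, 1] and the profile is linearly interpolated onto ``n_grid``
    evenly spaced points.
    """
    if cell.positions.size < 2:
        raise ValueError(f"cell {cell.cell_id}: need ≥2 points")
    top = float(np.max(cell.intensities))
    if top <= 0:
        raise ValueError(f"cell {cell.cell_id}: all-zero intensities")
    span = cell.positions[-1] - cell.positions[0]
    rel = (cell.positions - cell.positions[0]) / span
    grid = np.linspace(0.0, 1.0, n_grid)
    return np.interp(grid, rel, cell.intensities / top)


def average_profiles(cells: Sequence[NucleoidTransect], strain: str | None = None,
                     n_grid: int = 100) -> ProfileSummary:
    """Per-grid-point mean and standard error across cells."""
    if len(cells) < 2:
        raise ValueError("averaging needs ≥2 cells")
    strains = {c.strain for c in cells}
    if strain is None:
        if len(strains) > 1:
            raise ValueError(f"cells from multiple strains: {sorted(strains)}")
        strain = next(iter(strains))
    profiles = np.stack([normalize_and_resample(c, n_grid) for c in cells])
    return ProfileSummary(
        strain=strain,
        grid=np.linspace(0.0, 1.0, n_grid),
        mean=profiles.mean(axis=0),
        se=profiles.std(axis=0, ddof=1) / np.sqrt(len(cells)),
        n_cells=len(cells),
    )


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def _pooled_D(a: np.ndarray, b: np.ndarray) -> float:
    """sup |ECDF_a − ECDF_b| over the pooled sample."""
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def compare_ks(cells_a: Sequence[NucleoidTransect],
               cells_b: Sequence[NucleoidTransect],
               n_comparisons: int = 1, n_grid: int = 100,
               n_permutations: int = 999, seed: int = 0) -> KSComparison:
    """Two-sample KS test between two strains' pooled intensity values.

    ``D`` is the KS statistic between the pooled normalised intensities.
    With ``n_permutations > 0`` the P value is obtained by permuting cell
    labels between the strains (valid despite within-cell dependence);
    with 0 it is the asymptotic KS P treating pooled values as
    independent.  The raw P is Bonferroni-multiplied by
    ``n_comparisons`` and capped at 1.
    """
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("both strains need ≥2 cells")
    prof_a = np.stack([normalize_and_resample(c, n_grid) for c in cells_a])
    prof_b = np.stack([normalize_and_resample(c, n_grid) for c in cells_b])
    pool_a, pool_b = prof_a.ravel(), prof_b.ravel()
    D = _pooled_D(pool_a, pool_b)

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        all_cells = np.concatenate([prof_a, prof_b], axis=0)
        n_a = prof_a.shape[0]
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(all_cells.shape[0])
            d = _pooled_D(all_cells[perm[:n_a]].ravel(),
                          all_cells[perm[n_a:]].ravel())
            if d >= D - 1e-12:
                exceed += 1
        p_raw = (1 + exceed) / (n_permutations + 1)
    else:
        p_raw = float(stats.ks_2samp(pool_a, pool_b, method="asymp").pvalue)

    strain_a = cells_a[0].strain
    strain_b = cells_b[0].strain
    return KSComparison(
        strain_a=strain_a, strain_b=strain_b, D=D,
        p_raw=float(p_raw),
        p_adjusted=float(min(1.0, p_raw * n_comparisons)),
        n_a=len(cells_a), n_b=len(cells_b),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

TRANSECT_COLUMNS = ["cell_id", "strain", "cell_length_um", "position_um",
                    "intensity"]


def read_transects_csv(path: str | Path) -> list[NucleoidTransect]:
    df = pd.read_csv(path)
    missing = [c for c in TRANSECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transect CSV missing columns {missing}")
    cells = []
    for (cell_id, strain), sub in df.groupby(["cell_id", "strain"], sort=True):
        sub = sub.sort_values("position_um")
        lengths = sub["cell_length_um"].unique()
        if len(lengths) != 1:
            raise ValueError(f"cell {cell_id}: inconsistent cell_length_um")
        cells.append(NucleoidTransect(
            cell_id=str(cell_id), strain=str(strain),
            cell_length=float(lengths[0]),
            positions=sub["position_um"].to_numpy(float),
            intensities=sub["intensity"].to_numpy(float),
        ))
    return cells


def profile_table(summary: ProfileSummary) -> pd.DataFrame:
    return pd.DataFrame({
        "strain": summary.strain,
        "grid": summary.grid,
        "mean": summary.mean,
        "se": summary.se,
        "n_cells": summary.n_cells,
    })
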