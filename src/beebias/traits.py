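"""Trait-space coverage, overlap and permutation nulls.

Species-level morphological traits (intertegular distance and tongue
length, both in mm) are first residualised on principal components of the
genus trait means, removing genus-mean effects and the pseudoreplication
that taxonomic clustering would otherwise inject. Groups of species (e.g.
managed vs wild, or the effort x centrality policy groups) are then
compared in the residualised plane through kernel-density estimates:

* :func:`kde2d` — bivariate Gaussian product-kernel density on a regular
  grid with a Silverman rule-of-thumb bandwidth per axis;
* :func:`isopleth_region` — the smallest highest-density cell set holding
  a given fraction of the mass;
* :func:`coverage_fraction`, :func:`overlap_and_unique`,
  :func:`centroid_distance` — the comparison statistics;
* :func:`permutation_null` — a seeded same-size random-subset null with
  the add-one p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "residualize_on_genus_pcs",
    "DensityGrid",
    "kde2d",
    "isopleth_region",
    "coverage_fraction",
    "overlap_and_unique",
    "OverlapResult",
    "permutation_null",
    "PermutationResult",
    "centroid_distance",
    "group_coverage_test",
    "trait_coverage_summary",
    "CoverageSummary",
]


def residualize_on_genus_pcs(
    traits: pd.DataFrame,
    n_pcs: int = 2,
    trait_columns: tuple[str, str] = ("itd", "tongue"),
) -> pd.DataFrame:
    """Residualise z-scored traits on principal components of genus means.

    ``traits`` must have ``species``, ``genus`` and the two trait columns,
    complete cases only. Each trait is z-scored over species; the PCs are
    extracted from the genus-mean matrix (one row per genus, so large genera
    do not dominate the genus-level axes); every species inherits its genus'
    PC scores; least-squares residuals of each z-scored trait on those
    scores (plus intercept) are returned as columns ``x`` and ``y``.
    """
    if n_pcs not in (1, 2):
        raise ValueError("n_pcs must be 1 or 2")
    df = traits.dropna(subset=list(trait_columns)).copy()
    genera = df["genus"].unique()
    if len(genera) < 3:
        raise ValueError("need >= 3 genera with complete traits")
    if len(genera) < n_pcs + 1:
        raise ValueError("fewer genera than n_pcs + 1: singular design")

    z = np.column_stack([
        (df[c] - df[c].mean()) / df[c].std(ddof=1) for c in trait_columns
    ])
    zdf = pd.DataFrame(z, columns=["z0", "z1"], index=df.index)
    zdf["genus"] = df["genus"].to_numpy()
    gm = zdf.groupby("genus")[["z0", "z1"]].mean()
    centred = gm.to_numpy() - gm.to_numpy().mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    scores = centred @ vt[:n_pcs].T  # genus-level PC scores
    genus_scores = {g: scores[i] for i, g in enumerate(gm.index)}

    design = np.column_stack(
        [np.ones(len(df))] + [np.array([genus_scores[g][k] for g in df["genus"]]) for k in range(n_pcs)]
    )
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    out = df[["species", "genus"]].copy()
    out["x"] = resid[:, 0]
    out["y"] = resid[:, 1]
    return out.reset_index(drop=True)


@dataclass
class DensityGrid:
    """A KDE evaluated on a regular grid. ``density`` has shape (nx, ny)."""

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    bandwidth: tuple[float, float]

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


def _silverman_bandwidth(v: np.ndarray) -> float:
    n = v.size
    sd = v.std(ddof=1)
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("zero-variance axis: KDE bandwidth undefined")
    return 0.9 * spread * n ** (-1 / 5)


def kde2d(
    points: np.ndarray,
    grid_size: tuple[int, int] = (200, 200),
    margin_bandwidths: float = 3.0,
    extent: tuple[float, float, float, float] | None = None,
) -> DensityGrid:
    """Gaussian product-kernel density with per-axis Silverman bandwidths.

    The grid spans the data range expanded by ``margin_bandwidths``
    bandwidths on each side (or an explicit ``extent``), so the density
    integrates to 1 over the grid to well within 1%.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 5:
        raise ValueError("need >= 5 points for a 2-D KDE")
    hx = _silverman_bandwidth(pts[:, 0])
    hy = _silverman_bandwidth(pts[:, 1])
    if extent is None:
        x0, x1 = pts[:, 0].min() - margin_bandwidths * hx, pts[:, 0].max() + margin_bandwidths * hx
        y0, y1 = pts[:, 1].min() - margin_bandwidths * hy, pts[:, 1].max() + margin_bandwidths * hy
    else:
        x0, x1, y0, y1 = extent
    gx = np.linspace(x0, x1, grid_size[0])
    gy = np.linspace(y0, y1, grid_size[1])
    n = pts.shape[0]
    ux = (gx[:, None] - pts[None, :, 0]) / hx
    uy = (gy[:, None] - pts[None, :, 1]) / hy
    phix = np.exp(-0.5 * ux**2) / np.sqrt(2 * np.pi)
    phiy = np.exp(-0.5 * uy**2) / np.sqrt(2 * np.pi)
    density = (phix @ phiy.T) / (n * hx * hy)
    return DensityGrid(gx, gy, density, (hx, hy))


def isopleth_region(grid: DensityGrid, level: float) -> np.ndarray:
    """Smallest highest-density set of cells containing >= ``level`` of mass.

    Cells are sorted by density and accumulated until the requested fraction
    of the grid's total mass is reached.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    d = grid.density.ravel()
    order = np.argsort(d)[::-1]
    cum = np.cumsum(d[order])
    target = level * d.sum()
    k = int(np.searchsorted(cum, target - 1e-12)) + 1
    mask = np.zeros(d.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(grid.density.shape)


def coverage_fraction(group_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """Cell-count fraction of the reference region covered by the group."""
    if group_mask.shape != reference_mask.shape:
        raise ValueError("masks must share a grid")
    ref = int(reference_mask.sum())
    if ref == 0:
        raise ValueError("empty reference region")
    return float(np.logical_and(group_mask, reference_mask).sum() / ref)


@dataclass
class OverlapResult:
    overlap_mass: float
    unique_mass_a: float
    unique_mass_b: float
    level: float


def overlap_and_unique(
    density_a: DensityGrid,
    density_b: DensityGrid,
    level: float = 0.95,
) -> OverlapResult:
    """Overlap mass and group-unique masses of two densities on one grid.

    ``overlap_mass = sum min(fA, fB) * cell_area`` (symmetric);
    ``unique_mass_a`` is the mass of A lying outside B's ``level`` isopleth
    region, and symmetrically for B.
    """
    if density_a.density.shape != density_b.density.shape:
        raise ValueError("densities must share a grid")
    area = density_a.cell_area
    overlap = float(np.minimum(density_a.density, density_b.density).sum() * area)
    mask_b = isopleth_region(density_b, level)
    mask_a = isopleth_region(density_a, level)
    unique_a = float(density_a.density[~mask_b].sum() * area)
    unique_b = float(density_b.density[~mask_a].sum() * area)
    return OverlapResult(overlap, unique_a, unique_b, level)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p_value: float
    tail: str

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())


def permutation_null(
    statistic_fn: Callable[[np.ndarray], float],
    pool: np.ndarray,
    group_size: int,
    observed: float,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "lower",
) -> PermutationResult:
    """Same-size random-subset null for a group statistic.

    Draws ``n_perm`` subsets of ``group_size`` rows from ``pool`` without
    replacement, applies ``statistic_fn`` to each, and returns the add-one
    p-value ``(1 + #{null at least as extreme}) / (n_perm + 1)`` for the
    requested tail ("lower", "upper" or "two").
    """
    pool = np.asarray(pool)
    if group_size >= len(pool):
        raise ValueError("group_size must be smaller than the pool")
    if n_perm < 99:
        raise ValueError("need n_perm >= 99")
    if tail not in ("lower", "upper", "two"):
        raise ValueError(f"unknown tail {tail!r}")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(len(pool), size=group_size, replace=False)
        null[b] = statistic_fn(pool[idx])
    eps = 1e-12
    if tail == "lower":
        hits = int(np.sum(null <= observed + eps))
    elif tail == "upper":
        hits = int(np.sum(null >= observed - eps))
    else:
        centre = null.mean()
        hits = int(np.sum(np.abs(null - centre) >= abs(observed - centre) - eps))
    return PermutationResult(observed, null, (1 + hits) / (n_perm + 1), tail)


def centroid_distance(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Euclidean distance between the coordinate means of two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


@dataclass
class GroupCoverageResult:
    coverage: float
    null_mean: float
    p_value: float
    n_group: int
    n_perm: int
    level: float


def group_coverage_test(
    coords: np.ndarray,
    group_mask: np.ndarray,
    level: float = 0.95,
    grid_size: tuple[int, int] = (200, 200),
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupCoverageResult:
    """Observed vs null coverage of the all-species isopleth by a group.

    The reference isopleth comes from all species; coverage is the fraction
    of its cells intersected by the group's isopleth (both at ``level``,
    KDEs evaluated on the shared all-species grid). The null redraws
    same-size species subsets at random; the test is lower-tailed (groups
    covering *less* space than chance).
    """
    coords = np.asarray(coords, dtype=float)
    group_mask = np.asarray(group_mask, dtype=bool)
    ref_grid = kde2d(coords, grid_size=grid_size)
    extent = (ref_grid.x[0], ref_grid.x[-1], ref_grid.y[0], ref_grid.y[-1])
    ref_mask = isopleth_region(ref_grid, level)

    def cov(points: np.ndarray) -> float:
        g = kde2d(points, grid_size=grid_size, extent=extent)
        return coverage_fraction(isopleth_region(g, level), ref_mask)

    observed = cov(coords[group_mask])
    res = permutation_null(
        cov, coords, int(group_mask.sum()), observed,
        n_perm=n_perm, seed=seed, tail="lower",
    )
    return GroupCoverageResult(observed, res.null_mean, res.p_value, int(group_mask.sum()), n_perm, level)


@dataclass
class CoverageSummary:
    overall: float
    managed: float | None
    wild: float | None
    n_universe: int
    n_measured: int


def trait_coverage_summary(
    species_universe: pd.DataFrame,
    traits: pd.DataFrame,
    trait_columns: tuple[str, str] = ("itd", "tongue"),
) -> CoverageSummary:
    """Fraction of the species universe with both focal traits measured.

    ``species_universe`` needs ``species`` and ``managed`` columns; the
    managed/wild strata are computed over their own universes.
    """
    if species_universe.empty:
        raise ValueError("empty species universe")
    measured = set(
        traits.dropna(subset=list(trait_columns))["species"]
    )
    uni = species_universe.drop_duplicates("species")
    has = uni["species"].isin(measured)
    overall = float(has.mean())

    managed = wild = None
    if "managed" in uni.columns:
        m = uni["managed"].astype(bool)
        if m.any():
            managed = float(has[m].mean())
        if (~m).any():
            wild = float(has[~m].mean())
    return CoverageSummary(overall, managed, wild, len(uni), int(has.sum()))
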