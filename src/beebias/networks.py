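"""Genus-level centrality from bipartite plant-pollinator matrices.

Networks are matrices of non-negative visitation weights with plants on
rows and pollinators on columns. For each (cleaned) network the module
computes, per pollinator column,

* species strength ``s_j = sum_i a_ij / r_i`` — the summed dependence of
  each plant on pollinator *j* (``r_i`` the plant's row total), so that
  ``sum_j s_j`` equals the number of plant rows;
* Bluethgen's complementary specialisation ``d_j = sum_i p'_ij
  ln(p'_ij / q_i)`` with ``p'_ij = a_ij / A_j`` (column-conditional use)
  and ``q_i = r_i / m`` (partner availability), standardised to
  ``d'_j = (d_j - d_min) / (d_max - d_min)`` in [0, 1] using the extremes
  attainable given the column total and the integer nature of counts.

Metrics are z-scored within each network, networks with fewer than three
matched pollinator genera are dropped, and per-genus summaries are
region-balanced: z-scores are averaged within regions first, then across
regions, falling back to an interaction-weighted pooled mean when no
region labels exist. Sensitivity analyses (leave-one-region-out, network
bootstrap of the centrality-effort rank correlation) operate on the same
aggregation path.

``d_max`` is attained by concentrating the whole column total on the
plant with the smallest availability ``q_i`` (KL divergence is convex, so
its maximum over the simplex is at a vertex). ``d_min`` minimises a
separable convex function over integer allocations summing to the column
total, for which incremental greedy allocation is exactly optimal; both
facts make the heuristic agree with exhaustive search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "InteractionNetwork",
    "clean_network",
    "parse_genus",
    "collapse_to_genus",
    "species_strength",
    "bluethgen_d",
    "d_bounds",
    "zscore_within_network",
    "network_metric_rows",
    "filter_small_networks",
    "aggregate_region_balanced",
    "spearman",
    "leave_one_region_out",
    "bootstrap_centrality_correlation",
]


@dataclass
class InteractionNetwork:
    """A plants x pollinators visitation matrix with metadata."""

    matrix: np.ndarray
    column_labels: list[str]
    network_id: str
    region: str | None = None
    weighted: bool = True
    row_labels: list[str] | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[1] != len(self.column_labels):
            raise ValueError("column_labels length must match matrix columns")


def clean_network(matrix: np.ndarray, orientation_hint: str = "pollinators_on_columns") -> np.ndarray:
    """Drop all-zero rows/columns; transpose if pollinators are on rows.

    Raises on negative entries and on matrices that are empty after
    cleaning. Idempotent on already-clean matrices.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if np.any(a < 0):
        raise ValueError("interaction matrix has negative entries")
    if orientation_hint == "pollinators_on_rows":
        a = a.T
    elif orientation_hint != "pollinators_on_columns":
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    a = a[a.sum(axis=1) > 0][:, a.sum(axis=0) > 0]
    if a.size == 0:
        raise ValueError("matrix is empty after removing zero rows/columns")
    return a


def parse_genus(label: str, synonym_map: Mapping[str, str] | None = None) -> str | None:
    """First whitespace token, capitalised, mapped through the synonym map."""
    tokens = label.strip().split()
    if not tokens:
        return None
    genus = tokens[0].capitalize()
    if synonym_map:
        genus = synonym_map.get(genus, genus)
    return genus


def collapse_to_genus(
    matrix: np.ndarray,
    column_labels: Sequence[str],
    synonym_map: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Sum pollinator columns sharing a parsed genus into one column each.

    Columns whose label parses to no genus are dropped. Output genus order
    follows first appearance.
    """
    a = np.asarray(matrix, dtype=float)
    genera: list[str] = []
    columns: dict[str, np.ndarray] = {}
    for j, label in enumerate(column_labels):
        genus = parse_genus(label, synonym_map)
        if genus is None:
            continue
        if genus in columns:
            columns[genus] = columns[genus] + a[:, j]
        else:
            genera.append(genus)
            columns[genus] = a[:, j].copy()
    if not genera:
        raise ValueError("no parsable pollinator genera")
    return np.column_stack([columns[g] for g in genera]), genera


def species_strength(matrix: np.ndarray) -> np.ndarray:
    """Per-column strength s_j = sum_i a_ij / r_i. Conserves the row count."""
    a = np.asarray(matrix, dtype=float)
    r = a.sum(axis=1)
    if np.any(r <= 0):
        raise ValueError("zero row total: matrix was not cleaned")
    return (a / r[:, None]).sum(axis=0)


def _d_value(column: np.ndarray, q: np.ndarray) -> float:
    total = column.sum()
    if total <= 0:
        raise ValueError("zero column total: matrix was not cleaned")
    p = column / total
    nz = p > 0
    d = float(np.sum(p[nz] * np.log(p[nz] / q[nz])))
    if not np.isfinite(d):
        raise ValueError("non-finite specialisation intermediate")
    return max(d, 0.0)


def _d_min_integer(total: int, q: np.ndarray) -> float:
    """Exact integer minimum of sum (k_i/A) ln(k_i/(A q_i)), sum k_i = A.

    Greedy incremental allocation; optimal because the objective is
    separable and convex in the integer allocation.
    """
    A = int(total)
    k = np.zeros(len(q), dtype=int)

    def f(ki: np.ndarray) -> np.ndarray:
        out = np.zeros(len(q))
        nz = ki > 0
        out[nz] = (ki[nz] / A) * np.log(ki[nz] / (A * q[nz]))
        return out

    current = f(k)
    delta = f(k + 1) - current
    for _ in range(A):
        i = int(np.argmin(delta))
        k[i] += 1
        fi_now = (k[i] / A) * np.log(k[i] / (A * q[i]))
        fi_next = ((k[i] + 1) / A) * np.log((k[i] + 1) / (A * q[i]))
        delta[i] = fi_next - fi_now
    return float(np.sum(f(k)))


def d_bounds(total: float, q: np.ndarray) -> tuple[float, float]:
    """(d_min, d_max) attainable for a column with this total and margins q.

    Integer totals use the exact integer minimum; non-integer (already
    normalised / continuous) weights use the continuous bounds d_min = 0,
    d_max = ln(1/min q).
    """
    d_max = float(np.log(1.0 / q.min()))
    if abs(total - round(total)) < 1e-9 and total >= 1:
        d_min = _d_min_integer(int(round(total)), q)
    else:
        d_min = 0.0
    return d_min, d_max


def bluethgen_d(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Bluethgen specialisation (d, d').

    d is the Kullback-Leibler divergence of a pollinator's partner use from
    partner availability; d' standardises by the attainable extremes. When
    the extremes coincide (the column total admits a single divergence
    value, e.g. one visit in an identity matrix), d' is 1 if that common
    value is positive — the pollinator is as specialised as the margins
    allow — and 0 otherwise.
    """
    a = np.asarray(matrix, dtype=float)
    m = a.sum()
    r = a.sum(axis=1)
    if np.any(r <= 0) or m <= 0:
        raise ValueError("matrix was not cleaned")
    q = r / m
    d = np.empty(a.shape[1])
    dprime = np.empty(a.shape[1])
    for j in range(a.shape[1]):
        d[j] = _d_value(a[:, j], q)
        d_min, d_max = d_bounds(a[:, j].sum(), q)
        span = d_max - d_min
        if span < 1e-12:
            dprime[j] = 1.0 if d_max > 1e-12 else 0.0
        else:
            dprime[j] = min(max((d[j] - d_min) / span, 0.0), 1.0)
    return d, dprime


def zscore_within_network(values: Sequence[float]) -> np.ndarray:
    """Sample-sd z-scores; all-equal input maps to zeros."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def network_metric_rows(
    networks: Sequence[InteractionNetwork],
    synonym_map: Mapping[str, str] | None = None,
    min_genera: int = 3,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-(network, genus) metric table with within-network z-scores.

    Each network is cleaned, collapsed to genus columns, scored (strength,
    d, d'), and z-scored within the network. Networks with fewer than
    ``min_genera`` matched pollinator genera are dropped; their ids are
    returned as the drop log.
    """
    rows = []
    dropped: list[str] = []
    for net in networks:
        a = clean_network(net.matrix)
        if a.shape != net.matrix.shape:
            keep_rows = net.matrix.sum(axis=1) > 0
            keep_cols = net.matrix.sum(axis=0) > 0
            labels = [l for l, k in zip(net.column_labels, keep_cols) if k]
            a = net.matrix[keep_rows][:, keep_cols]
        else:
            labels = list(net.column_labels)
        collapsed, genera = collapse_to_genus(a, labels, synonym_map)
        if len(genera) < min_genera:
            dropped.append(net.network_id)
            continue
        strength = species_strength(collapsed)
        d, dprime = bluethgen_d(collapsed)
        z_strength = zscore_within_network(strength)
        z_dprime = zscore_within_network(dprime)
        interactions = collapsed.sum(axis=0)
        for k, genus in enumerate(genera):
            rows.append(
                {
                    "network_id": net.network_id,
                    "region": net.region,
                    "genus": genus,
                    "strength": strength[k],
                    "d": d[k],
                    "dprime": dprime[k],
                    "z_strength": z_strength[k],
                    "z_dprime": z_dprime[k],
                    "interactions": float(interactions[k]),
                }
            )
    columns = [
        "network_id", "region", "genus", "strength", "d", "dprime",
        "z_strength", "z_dprime", "interactions",
    ]
    return pd.DataFrame(rows, columns=columns), dropped


def filter_small_networks(rows: pd.DataFrame, min_genera: int = 3) -> tuple[pd.DataFrame, list[str]]:
    """Drop whole networks with fewer than ``min_genera`` matched genera."""
    if rows.empty:
        return rows.copy(), []
    sizes = rows.groupby("network_id")["genus"].nunique()
    dropped = sorted(sizes.index[sizes < min_genera])
    return rows[~rows["network_id"].isin(dropped)].copy(), list(dropped)


def aggregate_region_balanced(rows: pd.DataFrame) -> pd.DataFrame:
    """Region-balanced mean z-strength per genus.

    For each genus: average z-scores within each labelled region, then take
    the unweighted mean across regions. Genera with no region labels fall
    back to an interaction-weighted pooled mean of z-scores. Returns columns
    genus, mean_z_strength, n_networks, n_regions.
    """
    out = []
    for genus, g in rows.groupby("genus", sort=True):
        labelled = g[g["region"].notna()]
        if len(labelled):
            region_means = labelled.groupby("region")["z_strength"].mean()
            mean_z = float(region_means.mean())
            n_regions = int(region_means.size)
        else:
            w = g["interactions"].to_numpy(dtype=float)
            z = g["z_strength"].to_numpy(dtype=float)
            mean_z = float(np.average(z, weights=w)) if w.sum() > 0 else float(z.mean())
            n_regions = 0
        out.append(
            {
                "genus": genus,
                "mean_z_strength": mean_z,
                "n_networks": int(g["network_id"].nunique()),
                "n_regions": n_regions,
            }
        )
    return pd.DataFrame(out, columns=["genus", "mean_z_strength", "n_networks", "n_regions"])


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "asymptotic",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) and p-value.

    ``method="asymptotic"`` uses the t-approximation; ``"permutation"``
    permutes one margin ``n_perm`` times with the add-one estimator.
    Constant input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if method == "asymptotic":
        return rho, float(res.pvalue)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    hits = 0
    for _ in range(n_perm):
        if abs(np.corrcoef(rx, rng.permutation(ry))[0, 1]) >= obs - 1e-12:
            hits += 1
    return rho, (1 + hits) / (n_perm + 1)


def _rho_against_effort(centrality: pd.DataFrame, effort_by_genus: Mapping[str, float]) -> tuple[float, float, int]:
    merged = centrality[centrality["genus"].isin(effort_by_genus)]
    if len(merged) < 3:
        raise ValueError("fewer than 3 genera with both centrality and effort")
    effort = np.asarray([effort_by_genus[g] for g in merged["genus"]], dtype=float)
    rho, p = spearman(merged["mean_z_strength"].to_numpy(), effort)
    return rho, p, len(merged)


def leave_one_region_out(
    rows: pd.DataFrame,
    effort_by_genus: Mapping[str, float],
) -> pd.DataFrame:
    """Centrality-effort rho recomputed after excluding each region in turn.

    Regions whose removal leaves fewer than three genera are flagged rather
    than computed.
    """
    regions = sorted(rows["region"].dropna().unique())
    if len(regions) < 2:
        raise ValueError("need >= 2 regions for leave-one-region-out")
    out = []
    for region in regions:
        kept = rows[(rows["region"].isna()) | (rows["region"] != region)]
        try:
            rho, p, n = _rho_against_effort(aggregate_region_balanced(kept), effort_by_genus)
            out.append({"excluded_region": region, "rho": rho, "p": p, "n_genera": n, "flagged": False})
        except ValueError:
            out.append({"excluded_region": region, "rho": np.nan, "p": np.nan, "n_genera": 0, "flagged": True})
    return pd.DataFrame(out)


@dataclass
class BootstrapResult:
    rho: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_skipped: int


def bootstrap_centrality_correlation(
    rows: pd.DataFrame,
    effort_by_genus: Mapping[str, float],
    B: int = 1000,
    seed: int | None = None,
) -> BootstrapResult:
    """Percentile bootstrap CI for the centrality-effort Spearman rho.

    Networks (not rows) are resampled with replacement; aggregation is
    rebuilt per resample. Degenerate resamples (constant vectors or < 3
    genera) are skipped and counted.
    """
    if B < 100:
        raise ValueError("need B >= 100 bootstrap iterations")
    rho_obs, _, _ = _rho_against_effort(aggregate_region_balanced(rows), effort_by_genus)
    ids = rows["network_id"].unique()
    groups = {nid: g for nid, g in rows.groupby("network_id")}
    rng = np.random.default_rng(seed)
    rhos = []
    skipped = 0
    for _ in range(B):
        sample = rng.choice(ids, size=len(ids), replace=True)
        boot = pd.concat(
            [groups[nid].assign(network_id=f"{nid}#{k}") for k, nid in enumerate(sample)],
            ignore_index=True,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, _, _ = _rho_against_effort(aggregate_region_balanced(boot), effort_by_genus)
        except ValueError:
            skipped += 1
            continue
        if np.isnan(rho):
            skipped += 1
            continue
        rhos.append(rho)
    lo, hi = np.percentile(rhos, [2.5, 97.5])
    return BootstrapResult(rho_obs, float(lo), float(hi), len(rhos), skipped)
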