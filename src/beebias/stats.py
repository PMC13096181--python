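"""Bias statistics for genus-level research effort.

The module gathers the inferential layer of the audit:

* popularity-scaled expectations — expected paper counts proportional to a
  public-interest score, with residuals and integer percent deviations;
* quadrant classification of genera in the effort x centrality plane into
  the four policy groups (LELC, LEHC, HELC, HEHC);
* log-log richness-effort scaling with HC3 robust standard errors,
  Cook's-distance/leverage influence flags and sensitivity refits;
* Welch's heteroscedastic one-way ANOVA and Games-Howell post-hoc
  contrasts with Benjamini-Hochberg adjustment, for family comparisons;
* binomial share-trend GLMs (two-column response) and early-vs-recent
  era share changes;
* negative-binomial count regression with a log link and a log-exposure
  offset, reported as incidence rate ratios with Wald intervals.

Count models are fixed-effects NB2 regressions (maximum likelihood over
coefficients and dispersion jointly, via statsmodels); the exposure offset
makes coefficients describe shares of the yearly total rather than
absolute counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "expected_from_popularity",
    "deviation_table",
    "classify_quadrants",
    "QuadrantAssignment",
    "richness_effort_scaling",
    "ScalingFit",
    "hc3_covariance",
    "welch_anova",
    "games_howell",
    "bh_adjust",
    "binomial_share_trend",
    "ShareTrendFit",
    "nb_glm",
    "NBFit",
    "era_share_change",
]


# ---------------------------------------------------------------------------
# popularity expectations
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def deviation_table(observed: Mapping[str, float], expected: Mapping[str, float]) -> pd.DataFrame:
    """Residuals and integer percent deviations from observed/expected pairs."""
    if set(observed) != set(expected):
        raise ValueError("observed and expected must cover the same genera")
    rows = []
    for genus in observed:
        exp = float(expected[genus])
        if exp <= 0:
            raise ValueError(f"non-positive expected count for {genus}")
        resid = float(observed[genus]) - exp
        rows.append(
            {
                "genus": genus,
                "observed": float(observed[genus]),
                "expected": exp,
                "residual": resid,
                "pct_deviation": _round_half_away(100.0 * resid / exp),
            }
        )
    return pd.DataFrame(rows)


def expected_from_popularity(
    observed: Mapping[str, float],
    popularity: Mapping[str, float],
) -> pd.DataFrame:
    """Expected counts under proportionality to popularity.

    ``expected_g = T * pop_g / sum(pop)`` with ``T = sum(observed)``, so the
    expected counts conserve the observed total exactly. Returns the
    observed/expected/residual/percent table.
    """
    if set(observed) != set(popularity):
        raise ValueError("observed and popularity must cover the same genera")
    pops = np.asarray([popularity[g] for g in observed], dtype=float)
    if np.any(pops <= 0):
        raise ValueError("popularity scores must be positive")
    total = float(sum(observed.values()))
    expected = {g: total * popularity[g] / pops.sum() for g in observed}
    return deviation_table(observed, expected)


# ---------------------------------------------------------------------------
# policy-group quadrants
# ---------------------------------------------------------------------------

@dataclass
class QuadrantAssignment:
    assignments: pd.DataFrame  # genus, effort, centrality, group
    effort_threshold: float
    centrality_threshold: float
    group_sizes: dict[str, int]
    managed_share: dict[str, float] | None = None


def classify_quadrants(
    effort: Mapping[str, float],
    centrality: Mapping[str, float],
    effort_threshold: float | None = None,
    centrality_threshold: float | None = None,
    managed: Mapping[str, bool] | None = None,
) -> QuadrantAssignment:
    """Classify genera into LELC/LEHC/HELC/HEHC policy groups.

    High effort means effort above the threshold (default: median of
    log10(effort + 1)); high centrality means centrality above its threshold
    (default: median). The four groups always partition the classified set
    (genera present in both inputs). Managed shares per group are computed
    when a managed flag mapping is supplied.
    """
    genera = sorted(set(effort) & set(centrality))
    if not genera:
        raise ValueError("no genera present in both effort and centrality")
    log_effort = {g: math.log10(effort[g] + 1) for g in genera}
    if effort_threshold is None:
        effort_threshold = float(np.median([log_effort[g] for g in genera]))
        effort_values = log_effort
    else:
        if not np.isfinite(effort_threshold):
            raise ValueError("effort threshold must be finite")
        effort_values = {g: float(effort[g]) for g in genera}
    if centrality_threshold is None:
        centrality_threshold = float(np.median([centrality[g] for g in genera]))
    if not np.isfinite(centrality_threshold):
        raise ValueError("centrality threshold must be finite")

    rows = []
    for g in genera:
        he = effort_values[g] > effort_threshold
        hc = centrality[g] > centrality_threshold
        group = ("HE" if he else "LE") + ("HC" if hc else "LC")
        rows.append(
            {
                "genus": g,
                "effort": float(effort[g]),
                "centrality": float(centrality[g]),
                "group": group,
            }
        )
    df = pd.DataFrame(rows)
    sizes = {g: int((df["group"] == g).sum()) for g in ("LELC", "LEHC", "HELC", "HEHC")}
    shares = None
    if managed is not None:
        df["managed"] = [bool(managed.get(g, False)) for g in df["genus"]]
        shares = {
            g: (float(df.loc[df["group"] == g, "managed"].mean()) if sizes[g] else float("nan"))
            for g in sizes
        }
    return QuadrantAssignment(df, float(effort_threshold), float(centrality_threshold), sizes, shares)


# ---------------------------------------------------------------------------
# richness-effort scaling
# ---------------------------------------------------------------------------

def hc3_covariance(X: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """HC3 sandwich covariance (XtX)^-1 Xt diag(e^2/(1-h)^2) X (XtX)^-1."""
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    if np.any(h >= 1 - 1e-12):
        raise ValueError("hat diagonal of 1: HC3 undefined")
    omega = (e / (1 - h)) ** 2
    return xtx_inv @ (X.T * omega) @ X @ xtx_inv


@dataclass
class RefitResult:
    slope: float
    ci: tuple[float, float]
    adj_r2: float
    n: int


@dataclass
class ScalingFit:
    slope: float
    intercept: float
    se: float
    ci: tuple[float, float]
    adj_r2: float
    n: int
    influence: pd.DataFrame  # genus, cooks_d, leverage, flagged
    refits: dict[str, RefitResult] = field(default_factory=dict)


def _ols_hc3(logx: np.ndarray, logy: np.ndarray) -> tuple[float, float, float, float]:
    X = sm.add_constant(logx)
    fit = sm.OLS(logy, X).fit(cov_type="HC3")
    return float(fit.params[1]), float(fit.params[0]), float(fit.bse[1]), float(fit.rsquared_adj)


def richness_effort_scaling(
    articles: Mapping[str, float],
    richness: Mapping[str, float],
    exclude_genera: Sequence[str] = ("Apis", "Bombus"),
    trim_top_fraction: float = 0.01,
) -> ScalingFit:
    """Log-log scaling of research effort with genus species richness.

    Fits OLS of log10(articles + 1) on log10(richness) with HC3 robust
    standard errors and a Wald 95% CI. Points with Cook's D > 4/n or
    leverage > 2p/n are flagged, and sensitivity refits are reported after
    (a) excluding flagged points, (b) excluding ``exclude_genera``, and
    (c/d) trimming the top ceil(1%) of genera by richness and by articles.
    """
    genera = sorted(set(articles) & set(richness))
    if len(genera) < 10:
        raise ValueError("need >= 10 genera for the scaling fit")
    logx = np.log10(np.asarray([richness[g] for g in genera], dtype=float))
    logy = np.log10(np.asarray([articles[g] for g in genera], dtype=float) + 1)
    if np.ptp(logx) == 0:
        raise ValueError("constant richness regressor")

    n, p = len(genera), 2
    X = sm.add_constant(logx)
    fit = sm.OLS(logy, X).fit(cov_type="HC3")
    infl = sm.OLS(logy, X).fit().get_influence()
    cooks = infl.cooks_distance[0]
    lev = infl.hat_matrix_diag
    flagged = (cooks > 4 / n) | (lev > 2 * p / n)
    influence = pd.DataFrame(
        {"genus": genera, "cooks_d": cooks, "leverage": lev, "flagged": flagged}
    )

    slope, intercept = float(fit.params[1]), float(fit.params[0])
    se = float(fit.bse[1])
    ci = (slope - 1.96 * se, slope + 1.96 * se)

    def refit(mask: np.ndarray) -> RefitResult:
        s, _, serr, r2 = _ols_hc3(logx[mask], logy[mask])
        return RefitResult(s, (s - 1.96 * serr, s + 1.96 * serr), r2, int(mask.sum()))

    refits: dict[str, RefitResult] = {}
    if flagged.any() and (~flagged).sum() >= 3:
        refits["influence_trimmed"] = refit(~flagged)
    named = np.array([g in set(exclude_genera) for g in genera])
    if named.any() and (~named).sum() >= 3:
        refits["exclude_named"] = refit(~named)
    k = int(math.ceil(trim_top_fraction * n))
    for key, values in (("trim_top_richness", logx), ("trim_top_articles", logy)):
        cutoff = np.sort(values)[-k:]
        mask = ~np.isin(np.arange(n), np.argsort(values)[-k:])
        if mask.sum() >= 3:
            refits[key] = refit(mask)
    return ScalingFit(slope, intercept, se, ci, float(fit.rsquared_adj), n, influence, refits)


# ---------------------------------------------------------------------------
# family comparisons
# ---------------------------------------------------------------------------

def welch_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, df1, df2, p).

    Each group needs >= 2 values and positive variance (groups below the
    size threshold are expected to be excluded upstream).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need >= 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs >= 2 values")
        if g.var(ddof=1) <= 0:
            raise ValueError("zero-variance group: Welch weights undefined")
    n = np.array([g.size for g in arrays], dtype=float)
    mean = np.array([g.mean() for g in arrays])
    var = np.array([g.var(ddof=1) for g in arrays])
    w = n / var
    W = w.sum()
    grand = (w * mean).sum() / W
    num = ((w * (mean - grand) ** 2).sum()) / (k - 1)
    lam = np.sum((1 - w / W) ** 2 / (n - 1))
    den = 1 + 2 * (k - 2) * lam / (k**2 - 1)
    F = num / den
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), float(df1), float(df2), p


def games_howell(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Games-Howell pairwise contrasts with BH-adjusted p-values.

    Uses unequal-variance standard errors, Welch-Satterthwaite degrees of
    freedom and the studentised-range reference distribution; the returned
    table has one row per unordered pair with difference, CI, raw p and
    ``p_adj`` (Benjamini-Hochberg across the k(k-1)/2 pairs).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    n = np.array([g.size for g in arrays], dtype=float)
    mean = np.array([g.mean() for g in arrays])
    var = np.array([g.var(ddof=1) for g in arrays])
    if np.any(n < 2) or np.any(var <= 0):
        raise ValueError("each group needs >= 2 values and positive variance")

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = var[i] / n[i] + var[j] / n[j]
            se = math.sqrt(se2)
            df = se2**2 / (
                (var[i] / n[i]) ** 2 / (n[i] - 1) + (var[j] / n[j]) ** 2 / (n[j] - 1)
            )
            diff = mean[i] - mean[j]
            q = abs(diff) / (se / math.sqrt(2))
            p = float(np.clip(sps.studentized_range.sf(q, k, df), 0, 1))
            q_crit = sps.studentized_range.ppf(1 - alpha, k, df)
            half = q_crit * se / math.sqrt(2)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "difference": diff,
                    "se": se,
                    "df": df,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    return table


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


# ---------------------------------------------------------------------------
# share trends and era changes
# ---------------------------------------------------------------------------

@dataclass
class ShareTrendFit:
    slope_per_year: float | None
    se: float | None
    p: float | None
    intercept: float | None
    flagged: bool
    reason: str | None = None


def _fit_share_glm(successes: np.ndarray, failures: np.ndarray, years: np.ndarray) -> ShareTrendFit:
    shares = successes / (successes + failures)
    if np.all(shares == 0) or np.all(shares == 1):
        return ShareTrendFit(None, None, None, None, True, "complete separation")
    X = sm.add_constant(years.astype(float))
    fit = sm.GLM(np.column_stack([successes, failures]), X, family=sm.families.Binomial()).fit()
    return ShareTrendFit(
        float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1]), float(fit.params[0]), False
    )


def binomial_share_trend(
    successes: Sequence[float],
    failures: Sequence[float],
    years: Sequence[int],
    levels: Mapping[str, Sequence[float]] | None = None,
) -> ShareTrendFit | pd.DataFrame:
    """Logit-linear trend of a share over years (two-column binomial GLM).

    Without ``levels``, fits share ~ year and returns the slope per calendar
    year on the logit scale. With ``levels`` (level -> per-year counts whose
    sum gives the totals), fits one-vs-rest GLMs per level and returns a
    table with BH-adjusted p-values.
    """
    successes = np.asarray(successes, dtype=float)
    failures = np.asarray(failures, dtype=float)
    years = np.asarray(years)
    totals = successes + failures
    if np.any(totals <= 0):
        raise ValueError("each year needs a positive total")
    if levels is None:
        return _fit_share_glm(successes, failures, years)

    counts = {lvl: np.asarray(v, dtype=float) for lvl, v in levels.items()}
    total = np.sum(list(counts.values()), axis=0)
    if np.any(total <= 0):
        raise ValueError("each year needs a positive total across levels")
    rows = []
    for lvl, succ in counts.items():
        fit = _fit_share_glm(succ, total - succ, years)
        rows.append(
            {
                "level": lvl,
                "slope_per_year": fit.slope_per_year,
                "se": fit.se,
                "p": fit.p,
                "flagged": fit.flagged,
            }
        )
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    adj = np.full(len(table), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(table.loc[ok, "p"].to_numpy())
    table["p_adj"] = adj
    return table


def era_share_change(
    counts: pd.DataFrame,
    early_window: tuple[int, int],
    recent_window: tuple[int, int],
    category_column: str = "category",
) -> pd.DataFrame:
    """Percentage-point change in category shares, recent minus early window.

    ``counts`` is tidy with columns year, ``category_column`` and count.
    The share of a category in a year is its count over the year total; the
    change is (mean share over the recent window - mean share over the early
    window) x 100.
    """
    for window in (early_window, recent_window):
        if not (counts["year"].between(*window)).any():
            raise ValueError(f"window {window} contains no data")

    def window_shares(window: tuple[int, int]) -> pd.Series:
        sub = counts[counts["year"].between(*window)]
        totals = sub.groupby("year")["count"].sum()
        if (totals <= 0).any():
            raise ValueError(f"window {window} has a zero-total year")
        shares = (
            sub.pivot_table(index="year", columns=category_column, values="count",
                            aggfunc="sum", fill_value=0)
            .div(totals, axis=0)
        )
        return shares.mean(axis=0)

    early = window_shares(early_window)
    recent = window_shares(recent_window)
    cats = sorted(set(early.index) | set(recent.index))
    rows = [
        {
            "category": c,
            "early_share": float(early.get(c, 0.0)),
            "recent_share": float(recent.get(c, 0.0)),
            "change_points": 100.0 * (float(recent.get(c, 0.0)) - float(early.get(c, 0.0))),
        }
        for c in cats
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# negative-binomial count model
# ---------------------------------------------------------------------------

@dataclass
class NBFit:
    params: pd.Series  # log-scale coefficients (no dispersion row)
    se: pd.Series
    irr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    theta: float
    converged: bool
    poisson_limit: bool
    loglike: float
    offset_description: str

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "irr": self.irr,
                "irr_ci_low": self.ci_low,
                "irr_ci_high": self.ci_high,
                "p": self.pvalues,
            }
        )


def nb_glm(
    counts: Sequence[float],
    X: pd.DataFrame | np.ndarray,
    offset: Sequence[float] | None = None,
    add_intercept: bool = True,
    offset_description: str = "log exposure",
) -> NBFit:
    """Negative-binomial (NB2) regression with log link and exposure offset.

    Coefficients and the dispersion are estimated jointly by maximum
    likelihood. Results are reported as incidence rate ratios
    ``exp(beta)`` with Wald 95% intervals ``exp(beta +- 1.96 se)``. The
    dispersion is returned as ``theta = 1/alpha`` (variance
    ``mu + mu^2/theta``); an essentially-zero alpha is flagged as the
    Poisson limit. Raises on non-convergence.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        design = X.to_numpy(dtype=float)
    else:
        design = np.asarray(X, dtype=float)
        if design.ndim == 1:
            design = design[:, None]
        names = [f"x{i}" for i in range(design.shape[1])]
    if add_intercept:
        design = np.column_stack([np.ones(len(y)), design])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    off = None
    if offset is not None:
        off = np.asarray(offset, dtype=float)
        if not np.all(np.isfinite(off)):
            raise ValueError("offset must be finite")

    model = sm.NegativeBinomial(y, design, offset=off)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, method="bfgs", maxiter=500)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise RuntimeError(f"negative-binomial fit did not converge: {res.mle_retvals}")

    beta = res.params[:-1]
    se = res.bse[:-1]
    alpha = float(res.params[-1])
    poisson_limit = alpha < 1e-4
    theta = float("inf") if poisson_limit else 1.0 / alpha
    idx = pd.Index(names)
    params = pd.Series(beta, index=idx)
    se_s = pd.Series(se, index=idx)
    return NBFit(
        params=params,
        se=se_s,
        irr=np.exp(params),
        ci_low=np.exp(params - 1.96 * se_s),
        ci_high=np.exp(params + 1.96 * se_s),
        pvalues=pd.Series(res.pvalues[:-1], index=idx),
        theta=theta,
        converged=converged,
        poisson_limit=poisson_limit,
        loglike=float(res.llf),
        offset_description=offset_description,
    )
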