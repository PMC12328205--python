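"""Palaeoclimatic niche statistics for occurrence data.

Occurrences get the four climate variables (MAT, MAP, seasonal variation in
temperature and in precipitation) from the nearest land grid cell of their
stage slice; records spanning two (or more) slices get per-variable means
and count as a single averaged stratigraphic occurrence. Downstream:
unit-variance PCA, permutation MANOVA (Pillai trace by default), pairwise
Wilcoxon rank-sum tests, Shapiro-Wilk normality diagnostics and
raincloud-style summaries whose whiskers run from the quartiles to the
extremes (no 1.5 IQR fence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .climate import ClimateGrid, VARIABLES, nearest_land_cell
from .occurrences import DEFAULT_STAGES, OccurrenceRecord, StageTable

__all__ = [
    "NicheError",
    "extract_climate",
    "assign_niche_groups",
    "ClimateNichePCA",
    "run_pca",
    "permutation_manova",
    "pairwise_wilcoxon",
    "distribution_diagnostics",
    "raincloud_summary",
]

PRE_NORIAN = ("Ladinian", "early Carnian", "late Carnian")
NORIAN_RHAETIAN = ("early Norian", "middle Norian", "late Norian", "Rhaetian")


class NicheError(ValueError):
    pass


def extract_climate(
    records: list[OccurrenceRecord],
    grids: dict,
    stages: StageTable = DEFAULT_STAGES,
    sea_fallback_cells: int = 5,
    strict: bool = False,
) -> pd.DataFrame:
    """Assign the four climate variables to each occurrence.

    ``grids`` maps slice name -> {variable -> ClimateGrid}. Values come
    from the nearest land cell (coastal occurrences fall back to the
    nearest land cell within ``sea_fallback_cells``); multi-slice records
    get the mean across their slices. Records whose stage span touches no
    modelled slice are skipped (or rejected when ``strict``).

    Returns a data frame with one row per usable record: identifiers,
    group label, and the four variables.
    """
    rows = []
    for rec in records:
        slices = stages.span(rec.stage_early, rec.stage_late)
        if not slices or not stages.span_resolves(rec.stage_early, rec.stage_late):
            if strict:
                raise NicheError(
                    f"{rec.specimen_id}: stage span {rec.stage_early}-{rec.stage_late} "
                    "has no climate slice"
                )
            continue
        values: dict[str, list[float]] = {v: [] for v in VARIABLES}
        ok = True
        for sl in slices:
            try:
                per_var = grids[sl]
            except KeyError:
                raise NicheError(f"no climate grids for slice {sl!r}")
            for var in VARIABLES:
                grid: ClimateGrid = per_var[var]
                cell = nearest_land_cell(
                    grid, rec.palaeolat, rec.palaeolon, sea_fallback_cells
                )
                if cell is None:
                    if strict:
                        raise NicheError(
                            f"{rec.specimen_id}: no land cell within "
                            f"{sea_fallback_cells} cells of "
                            f"({rec.palaeolat}, {rec.palaeolon}) in slice {sl}"
                        )
                    ok = False
                    break
                values[var].append(float(grid.values[cell]))
            if not ok:
                break
        if not ok:
            continue
        row = {
            "specimen_id": rec.specimen_id,
            "taxon": rec.taxon,
            "clade": rec.clade,
            "locality_id": rec.locality_id,
            "palaeolat": rec.palaeolat,
            "palaeolon": rec.palaeolon,
            "stage_early": rec.stage_early,
            "stage_late": rec.stage_late,
            "n_slices": len(slices),
            "group": _group_label(rec, stages),
        }
        for var in VARIABLES:
            row[var] = float(np.mean(values[var]))
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        if not np.isfinite(df[list(VARIABLES)].to_numpy()).all():
            raise NicheError("non-finite climate values extracted")
    return df


def _group_label(rec: OccurrenceRecord, stages: StageTable) -> str:
    """Niche-comparison group, or "" when the record straddles groups."""
    if rec.clade == "pterosaur":
        return "pterosaur"
    if rec.clade != "lagerpetid":
        return rec.clade
    span = stages.span(rec.stage_early, rec.stage_late)
    if all(s in PRE_NORIAN for s in span):
        return "pre-Norian lagerpetid"
    if all(s in NORIAN_RHAETIAN for s in span):
        return "Norian-Rhaetian lagerpetid"
    return ""


def assign_niche_groups(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows that straddle the pre-Norian/Norian group boundary."""
    return df[df["group"] != ""].reset_index(drop=True)


class ClimateNichePCA(TransformerMixin, BaseEstimator):
    """PCA of climate variables scaled to unit variance.

    All components are kept; the sign convention makes the largest-magnitude
    loading of each component positive. After :meth:`fit`: ``mean_``,
    ``scale_`` (SD, ddof=1), ``loadings_`` (n_vars x n_comp, orthonormal
    columns), ``explained_variance_``, ``explained_variance_ratio_``.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise NicheError("PCA needs a 2-D matrix with at least 3 rows")
        if not np.isfinite(X).all():
            raise NicheError("PCA input contains missing or non-finite values")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ <= 0):
            bad = int(np.argmin(self.scale_))
            raise NicheError(f"column {bad} has zero variance and cannot be scaled")
        Z = (X - self.mean_) / self.scale_
        pca = PCA(n_components=min(X.shape), svd_solver="full")
        pca.fit(Z)
        comps = pca.components_  # (n_comp, n_vars)
        signs = np.sign(comps[np.arange(len(comps)), np.argmax(np.abs(comps), axis=1)])
        signs[signs == 0] = 1.0
        comps = comps * signs[:, None]
        self.loadings_ = comps.T
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_components_ = comps.shape[0]
        return self

    def transform(self, X):
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return Z @ self.loadings_


@dataclass
class NicheOrdination:
    standardized: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def run_pca(data) -> NicheOrdination:
    """Functional wrapper over :class:`ClimateNichePCA`."""
    X = np.asarray(data, dtype=float)
    est = ClimateNichePCA().fit(X)
    Z = (X - est.mean_) / est.scale_
    return NicheOrdination(
        standardized=Z,
        scores=est.transform(X),
        loadings=est.loadings_,
        explained_variance=est.explained_variance_,
        explained_variance_ratio=est.explained_variance_ratio_,
    )


def _pillai_stats(X: np.ndarray, group_sizes: np.ndarray, perm_rows: np.ndarray,
                  stat: str) -> np.ndarray:
    """Test statistics for label permutations given by ``perm_rows``.

    Rows are pre-sorted so group g occupies a contiguous slice. The total
    (centred) SSCP is permutation-invariant, so only the between-group
    matrix H is recomputed per permutation.
    """
    n, p = X.shape
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    bounds = np.concatenate([[0], np.cumsum(group_sizes)])
    out = np.empty(len(perm_rows))
    if stat == "pillai":
        Tinv = np.linalg.pinv(T)
    for i, rows in enumerate(perm_rows):
        Xp = Xc[rows]
        H = np.zeros((p, p))
        for g in range(len(group_sizes)):
            seg = Xp[bounds[g]: bounds[g + 1]]
            m = seg.mean(axis=0)
            H += len(seg) * np.outer(m, m)
        if stat == "pillai":
            out[i] = float(np.trace(H @ Tinv))
        else:  # wilks lambda; smaller = stronger effect, invert sign ordering
            E = T - H
            sign, logdetE = np.linalg.slogdet(E)
            _, logdetT = np.linalg.slogdet(T)
            out[i] = -(logdetE - logdetT)  # -log Lambda, larger = stronger
    return out


@dataclass
class ManovaResult:
    statistic: float
    p_value: float
    stat_name: str
    n_perm: int
    pairwise: pd.DataFrame | None = None


def permutation_manova(
    data,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    pairwise: bool = False,
    stat: str = "pillai",
    scale: bool = True,
) -> ManovaResult:
    """Non-parametric MANOVA of a multivariate response on group labels.

    The observed statistic (Pillai trace by default, Wilks selectable) is
    compared with its distribution under ``n_perm`` random label
    permutations; p = (1 + #{perm >= obs}) / (1 + n_perm). Pairwise mode
    additionally tests each group pair and applies Benjamini-Hochberg FDR.
    A seed is required for reproducibility.
    """
    if n_perm < 99:
        raise NicheError("n_perm must be at least 99")
    if stat not in ("pillai", "wilks"):
        raise NicheError("stat must be 'pillai' or 'wilks'")
    if seed is None:
        raise NicheError("a seed is required for the permutation stream")
    X = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise NicheError("need at least 2 groups")
    if counts.min() < 3:
        raise NicheError("every group needs at least 3 members")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise NicheError("constant column cannot be scaled")
        X = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(seed)
    order = np.argsort(groups, kind="stable")  # group-contiguous layout
    Xs = X[order]
    sizes = counts
    n = len(Xs)
    perms = np.empty((n_perm + 1, n), dtype=int)
    perms[0] = np.arange(n)
    for i in range(1, n_perm + 1):
        perms[i] = rng.permutation(n)
    stats_all = _pillai_stats(Xs, sizes, perms, stat)
    obs = stats_all[0]
    p = (1.0 + np.sum(stats_all[1:] >= obs - 1e-12)) / (1.0 + n_perm)

    pairwise_df = None
    if pairwise:
        rows = []
        for a, b in combinations(labels, 2):
            mask = (groups == a) | (groups == b)
            sub = permutation_manova(
                np.asarray(data, dtype=float)[mask], groups[mask],
                n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                pairwise=False, stat=stat, scale=scale,
            )
            rows.append({"group_a": a, "group_b": b,
                         "statistic": sub.statistic, "p": sub.p_value})
        pairwise_df = pd.DataFrame(rows)
        pairwise_df["p_adjusted"] = multipletests(pairwise_df["p"], method="fdr_bh")[1]
    return ManovaResult(
        statistic=float(obs), p_value=float(p), stat_name=stat,
        n_perm=n_perm, pairwise=pairwise_df,
    )


def pairwise_wilcoxon(values, groups, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Wilcoxon rank-sum (Mann-Whitney) tests for every group pair.

    Exact enumeration when both samples have n <= 20 and no ties span the
    two samples; tie-corrected normal approximation otherwise. All-tied
    input yields p = 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    rows = []
    for a, b in combinations(labels, 2):
        x, y = values[groups == a], values[groups == b]
        if len(x) < 2 or len(y) < 2:
            raise NicheError("each group needs n >= 2")
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn(f"all values tied for {a} vs {b}; p = 1")
            rows.append({"group_a": a, "group_b": b, "statistic": np.nan, "p": 1.0})
            continue
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append({"group_a": a, "group_b": b,
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    if adjust and len(df):
        df["p_adjusted"] = multipletests(df["p"], method=adjust)[1]
    return df


def distribution_diagnostics(values) -> dict:
    """Shapiro-Wilk W and p plus a quantile-quantile linear summary."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise NicheError("normality diagnostics need n >= 3")
    if len(x) > 5000:
        raise NicheError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0:
        raise NicheError("constant input has no distribution shape")
    w, p = stats.shapiro(x)
    (osm, osr), (slope, intercept, r) = stats.probplot(x, dist="norm")
    return {
        "n": len(x),
        "shapiro_w": float(w),
        "shapiro_p": float(p),
        "qq_slope": float(slope),
        "qq_intercept": float(intercept),
        "qq_r": float(r),
    }


def raincloud_summary(values, groups, kde_points: int = 128) -> dict:
    """Per-group box summary (linear-interpolation quantiles) and kernel
    density trace. Whiskers run from the quartiles to the extreme values."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        x = values[groups == g]
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        entry = {
            "n": int(len(x)),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(x.min()),
            "whisker_high": float(x.max()),
            "kde": None,
        }
        if len(x) >= 2 and np.ptp(x) > 0:
            kde = stats.gaussian_kde(x)
            lo, hi = x.min(), x.max()
            pad = 0.1 * (hi - lo)
            xs = np.linspace(lo - pad, hi + pad, kde_points)
            entry["kde"] = (xs, kde(xs))
        out[g] = entry
    return out
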