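"""Biomarker preprocessing: normality checks, log transform, covariate
regression, group comparisons with FDR control, and bootstrapped rank-based
region selection.

Disconnectivity fractions are heavily right-skewed (many subjects have little
or no disconnection in a given region), so group comparisons are run on
log-transformed values; a small epsilon keeps zeros finite. Region selection
ranks regions by the two-sample t statistic (positive = higher disconnectivity
in the more-impaired group) within each of ``n_boot`` stratified bootstrap
resamples, and keeps the ``top_k`` regions with the best (smallest) average
rank — a stability-driven alternative to selecting on a single t pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normality_check",
    "log_transform",
    "regress_out_covariates",
    "group_ttest",
    "bh_adjust",
    "bootstrap_rank_selection",
    "SelectionResult",
    "TTestResult",
]


def normality_check(matrix: np.ndarray, region_ids=None) -> pd.DataFrame:
    """Shapiro–Wilk test per region.

    Returns a tidy frame (region_id, W, p, skipped); constant columns are
    flagged and skipped. Summary means over the tested columns are available
    as ``df["W"].mean()`` / ``df["p"].mean()``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("Shapiro–Wilk needs at least 3 observations per region")
    ids = region_ids if region_ids is not None else [str(j) for j in range(X.shape[1])]
    rows = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            rows.append((ids[j], np.nan, np.nan, True))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w, p = stats.shapiro(col)
        rows.append((ids[j], w, p, False))
    return pd.DataFrame(rows, columns=["region_id", "W", "p", "skipped"])


def log_transform(matrix: np.ndarray, epsilon: float = 1e-2) -> np.ndarray:
    """Elementwise ``log(x + epsilon)``; strictly increasing, invertible."""
    X = np.asarray(matrix, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if (X < 0).any():
        raise ValueError("log transform requires non-negative values")
    return np.log(X + epsilon)


def regress_out_covariates(matrix: np.ndarray, age, sex) -> np.ndarray:
    """OLS-residualize every region on intercept + age + sex.

    Residuals have mean zero per region and are orthogonal to both covariates.
    """
    Y = np.asarray(matrix, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    n = Y.shape[0]
    if n <= 3:
        raise ValueError("need more than 3 subjects to fit intercept + age + sex")
    X = np.column_stack([np.ones(n), age, sex])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("covariates are collinear or constant; cannot residualize")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ beta


class TTestResult(NamedTuple):
    t: np.ndarray
    p: np.ndarray
    undefined: np.ndarray  # zero pooled variance with unequal means


def group_ttest(matrix: np.ndarray, group_labels) -> TTestResult:
    """Two-sample pooled-variance (Student) t per region.

    Sign convention: positive t means the group-1 (more severe) mean is
    larger. Zero-pooled-variance columns yield t=0, p=1 when the group means
    agree, and are flagged undefined otherwise.
    """
    X = np.asarray(matrix, dtype=float)
    g = np.asarray(group_labels, dtype=int)
    if not np.isin(g, [0, 1]).all():
        raise ValueError("group labels must be 0/1")
    x0, x1 = X[g == 0], X[g == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs at least 2 subjects")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(x1, x0, equal_var=True, axis=0)
    t, p = np.atleast_1d(np.asarray(t, float)), np.atleast_1d(np.asarray(p, float))
    # detect zero pooled variance by range, not var(): the two-pass variance of
    # a constant column can come out ~1e-30 and yield junk t instead of nan
    zero_var = (np.ptp(x0, axis=0) == 0) & (np.ptp(x1, axis=0) == 0)
    same_mean = np.isclose(x0.mean(axis=0), x1.mean(axis=0))
    fix = zero_var & same_mean
    t[fix], p[fix] = 0.0, 1.0
    undefined = zero_var & ~same_mean
    t[undefined], p[undefined] = np.nan, np.nan
    return TTestResult(t, p, undefined)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, p_adj < alpha


@dataclass
class SelectionResult:
    """Outcome of bootstrapped rank-based region selection."""

    selected_regions: list[str]
    mean_ranks: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    p_adjusted: np.ndarray
    region_ids: list[str]
    n_boot_effective: int

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected_regions)
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "t": self.t_stats,
                "p": self.p_values,
                "p_adj": self.p_adjusted,
                "mean_rank": self.mean_ranks,
                "selected": [r in sel for r in self.region_ids],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def bootstrap_rank_selection(
    matrix: np.ndarray,
    group_labels,
    n_boot: int = 100,
    top_k: int = 20,
    seed: int | None = None,
    region_ids=None,
    resample: bool = True,
) -> SelectionResult:
    """Select the ``top_k`` regions with the best average t-statistic rank
    across stratified bootstrap resamples.

    Each bootstrap resamples subjects with replacement within each group
    (preserving group sizes); regions are ranked 1..P by descending t (rank 1
    = largest t). Bootstraps where any region's t is undefined are skipped and
    counted out of ``n_boot_effective``. ``resample=False`` is a test hook: it
    repeats the full sample, reducing selection to ranking by the full-sample
    t. Ties in mean rank break toward the smaller region index.
    """
    X = np.asarray(matrix, dtype=float)
    g = np.asarray(group_labels, dtype=int)
    n, p = X.shape
    if top_k > p:
        raise ValueError(f"top_k={top_k} exceeds {p} regions")
    ids = list(region_ids) if region_ids is not None else [str(j) for j in range(p)]
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.flatnonzero(g == 0), np.flatnonzero(g == 1)

    rank_sum = np.zeros(p)
    n_eff = 0
    for _ in range(n_boot):
        if resample:
            rows = np.concatenate(
                [rng.choice(idx0, size=len(idx0), replace=True),
                 rng.choice(idx1, size=len(idx1), replace=True)]
            )
        else:
            rows = np.arange(n)
        t, _, undef = group_ttest(X[rows], g[rows])
        if undef.any():
            # zero within-group variance with unequal means: the region
            # separates the groups perfectly — rank it at the corresponding
            # extreme rather than discarding the bootstrap
            Xb, gb = X[rows], g[rows]
            diff = Xb[gb == 1].mean(axis=0) - Xb[gb == 0].mean(axis=0)
            t = t.copy()
            t[undef] = np.where(diff[undef] > 0, np.inf, -np.inf)
        if np.isnan(t).any():
            continue
        rank_sum += stats.rankdata(-t, method="average")
        n_eff += 1
    if n_eff == 0:
        raise ValueError("every bootstrap was degenerate; cannot rank regions")
    if n_eff < n_boot:
        warnings.warn(f"skipped {n_boot - n_eff} degenerate bootstrap(s)", stacklevel=2)
    mean_ranks = rank_sum / n_eff

    # lexsort: primary key mean rank, ties toward the smaller region index;
    # selected list kept in mean-rank order (best first)
    order = np.lexsort((np.arange(p), mean_ranks))
    selected = [ids[j] for j in order[:top_k]]

    t_full, p_full, undef_full = group_ttest(X, g)
    p_for_adjust = np.where(np.isnan(p_full), 1.0, p_full)
    p_adj, _ = bh_adjust(p_for_adjust)
    return SelectionResult(
        selected_regions=selected,
        mean_ranks=mean_ranks,
        t_stats=t_full,
        p_values=p_full,
        p_adjusted=p_adj,
        region_ids=ids,
        n_boot_effective=n_eff,
    )
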