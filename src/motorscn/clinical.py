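"""Non-network statistics: demographic contingency tests, covariate-adjusted
global volume comparisons, brain-behaviour partial correlations and the
a-priori one-way-ANOVA sample-size computation."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import COVARIATES, CohortTable

logger = logging.getLogger("motorscn")


# ---------------------------------------------------------------------------
# 2x2 chi-square
# ---------------------------------------------------------------------------

def chi_square_2x2(table: np.ndarray | Sequence[Sequence[int]],
                   continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1.

    No Yates continuity correction by default (``continuity=True`` enables
    it).  Raises on zero marginals / non-positive expected counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, _, expected = stats.chi2_contingency(t, correction=continuity)
    if (expected <= 0).any():
        raise ValueError("non-positive expected count")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Covariate-adjusted global volume comparison (ANCOVA + pairwise contrasts)
# ---------------------------------------------------------------------------

@dataclass
class VolumeComparison:
    measure: str
    adjusted_means: dict[str, float]
    contrasts: pd.DataFrame       # pair, estimate, t, p (model-based)


def compare_global_volumes(cohort: CohortTable, measure: str,
                           covariates: Sequence[str] = ("age",)
                           ) -> VolumeComparison:
    """ANCOVA of a global structural measure (TIV, GM_total, WM_total, or any
    cohort column) on group, controlling for the covariates; adjusted group
    means at the covariate mean and all pairwise model-based contrasts."""
    df = cohort.data
    if measure not in df.columns:
        raise ValueError(f"measure {measure!r} not in cohort")
    groups = sorted(df["group"].unique())
    y = df[measure].to_numpy(dtype=float)
    C = df[list(covariates)].to_numpy(dtype=float)
    G = np.column_stack([(df["group"] == g).to_numpy(float) for g in groups[1:]])
    X = sm.add_constant(np.column_stack([G, C - C.mean(axis=0)]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design (constant covariate or empty group)")
    fit = sm.OLS(y, X).fit()

    coef = dict(zip(groups[1:], fit.params[1:1 + len(groups) - 1]))
    base = fit.params[0]
    adjusted = {groups[0]: float(base)}
    adjusted.update({g: float(base + coef[g]) for g in groups[1:]})

    rows = []
    p_total = X.shape[1]
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            contrast = np.zeros(p_total)
            if a > 0:
                contrast[a] = 1.0
            if b > 0:
                contrast[b] = -1.0
            tt = fit.t_test(contrast)
            rows.append({"pair": f"{groups[a]} vs {groups[b]}",
                         "estimate": float(np.atleast_1d(tt.effect)[0]),
                         "t": float(np.atleast_1d(tt.tvalue).ravel()[0]),
                         "p": float(np.atleast_1d(tt.pvalue).ravel()[0])})
    return VolumeComparison(measure, adjusted, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Brain-behaviour partial correlations
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrelationResult:
    roi: str
    score: str
    r_partial: float
    p: float
    p_fdr: float
    n: int
    covariates: tuple[str, ...]


def partial_correlation(x: np.ndarray, y: np.ndarray, covars: np.ndarray
                        ) -> tuple[float, float, int]:
    """Residual-on-residual Pearson partial correlation with a t-based
    two-sided p (df = n - 2 - k)."""
    X = np.column_stack([np.ones(len(x)), covars])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    n, k = len(x), covars.shape[1]
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"insufficient df ({df}) for partial correlation")
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan"), n
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p), n


def brain_behaviour(cohort: CohortTable, rois: Sequence[str] | None = None,
                    scores: Sequence[str] | None = None,
                    group: str | None = None,
                    covariates: Sequence[str] = COVARIATES
                    ) -> list[PartialCorrelationResult]:
    """Partial correlation of each ROI volume with each motor score, given
    age, sex and TIV; Benjamini-Hochberg across the ROI x score grid.

    Subjects missing a score are dropped per score; constant scores within
    the subgroup are flagged missing (NaN) with a warning.
    """
    df = cohort.data if group is None else cohort.data[cohort.data["group"] == group]
    rois = list(rois) if rois is not None else cohort.atlas.names
    scores = list(scores) if scores is not None else cohort.score_columns
    results: list[PartialCorrelationResult] = []
    for score in scores:
        ok = df[score].notna()
        sub = df[ok]
        y = sub[score].to_numpy(dtype=float)
        covars = sub[list(covariates)].to_numpy(dtype=float)
        constant = y.std() == 0
        if constant:
            logger.warning("score %r constant in subgroup; results flagged missing",
                           score)
        for roi in rois:
            if constant or len(sub) - 2 - covars.shape[1] <= 0:
                results.append(PartialCorrelationResult(
                    roi, score, float("nan"), float("nan"), float("nan"),
                    len(sub), tuple(covariates)))
                continue
            x = sub[roi].to_numpy(dtype=float)
            r, p, n = partial_correlation(x, y, covars)
            results.append(PartialCorrelationResult(
                roi, score, r, p, float("nan"), n, tuple(covariates)))
    praw = np.array([res.p for res in results])
    finite = np.isfinite(praw)
    if finite.any():
        _, pfdr, *_ = multipletests(praw[finite], method="fdr_bh")
        it = iter(pfdr)
        for i in np.flatnonzero(finite):
            results[i].p_fdr = float(next(it))
    return results


def behaviour_table(results: list[PartialCorrelationResult]) -> pd.DataFrame:
    """Long-format table, heatmap-ready (roi x score grid)."""
    return pd.DataFrame([{"roi": r.roi, "score": r.score, "r_partial": r.r_partial,
                          "p": r.p, "p_fdr": r.p_fdr, "n": r.n} for r in results])


def behaviour_heatmap(results: list[PartialCorrelationResult], path=None):
    """Optional plotting helper: ROI x score heatmap of partial correlations
    annotated with p-values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = behaviour_table(results).pivot(index="roi", columns="score",
                                           values="r_partial")
    pmat = behaviour_table(results).pivot(index="roi", columns="score", values="p")
    fig, ax = plt.subplots(figsize=(1.2 * table.shape[1] + 2,
                                    0.4 * table.shape[0] + 1))
    im = ax.imshow(table.to_numpy(), cmap="viridis", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=45, ha="right")
    ax.set_yticks(range(table.shape[0]), table.index)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            r, p = table.iat[i, j], pmat.iat[i, j]
            if np.isfinite(r):
                ax.text(j, i, f"{r:.2f}\np={p:.3f}", ha="center", va="center",
                        fontsize=6)
    fig.colorbar(im, ax=ax, label="partial r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# A-priori sample size for one-way ANOVA
# ---------------------------------------------------------------------------

def anova_power(n_total: int, k_groups: int, effect_f: float,
                alpha: float = 0.05) -> float:
    """Power of the one-way ANOVA F test with Cohen's f effect size.

    Noncentrality lambda = f^2 * N; df = (k - 1, N - k); power from the
    noncentral-F distribution.
    """
    if n_total <= k_groups:
        raise ValueError("need N > k for positive error df")
    df1, df2 = k_groups - 1, n_total - k_groups
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(1.0 - stats.ncf.cdf(fcrit, df1, df2, effect_f**2 * n_total))


def min_sample_size_anova(k_groups: int = 3, effect_f: float = 0.40,
                          alpha: float = 0.05, power: float = 0.80,
                          n_cap: int = 10**6) -> int:
    """Smallest balanced total N (a multiple of k) reaching the target power.

    Balanced allocation with n per group >= 2, i.e. candidates N = 2k, 3k, ...
    """
    if effect_f <= 0 or not (0 < alpha < 1) or not (0 < power < 1) or k_groups < 2:
        raise ValueError("invalid power query")
    n = 2 * k_groups
    while n <= n_cap:
        if anova_power(n, k_groups, effect_f, alpha) >= power:
            return n
        n += k_groups
    raise RuntimeError(f"target power unreachable below N = {n_cap}")
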