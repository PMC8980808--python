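"""PCA machinery, loading-matrix similarity, and nonparametric group tests.

The dimensionality-reduction conventions used throughout the analysis live
here: column z-scoring, full-rank PCA with a deterministic sign convention
(each component's largest-magnitude loading is positive), the smallest
number of components reaching 80% cumulative variance, a multi-group PCA
(per-group z-scoring, pooled fit on the stacked standardized rows),
Pearson correlation of PC scores across models, and a structural
similarity index (SSIM) between loading matrices used to quantify whether
two PCAs extracted the same structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger(__name__)

VARIANCE_THRESHOLD = 0.80

# SSIM stabilizing constants for a dynamic range of 2 (loadings in [-1, 1])
SSIM_L = 2.0
SSIM_C1 = (0.01 * SSIM_L) ** 2
SSIM_C2 = (0.03 * SSIM_L) ** 2


@dataclass
class PCAModel:
    """A fitted PCA: loadings, explained-variance fractions, scores.

    ``loadings`` is features × components (orthonormal columns, sign
    convention applied); ``scores`` is subjects × components for the
    ``n_used`` subjects that entered the fit.
    """

    loadings: pd.DataFrame
    explained: np.ndarray
    scores: pd.DataFrame
    n_used: int

    @property
    def feature_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass(frozen=True)
class SimilarityResult:
    """Loading-matrix similarity in [0, 1] and the component count compared."""

    value: float
    k_used: int


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each column to mean 0, SD 1 (n−1 denominator).

    Missing cells stay missing. Constant columns are dropped with a
    warning; an all-missing column is an error naming the column.
    """
    table = pd.DataFrame(table)
    out = {}
    for col in table.columns:
        vals = table[col]
        n = vals.notna().sum()
        if n == 0:
            raise ValueError(f"column {col!r} is entirely missing")
        if n < 2:
            raise ValueError(f"column {col!r} has fewer than 2 non-missing values")
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"dropping constant column {col!r}", stacklevel=2)
            continue
        out[col] = (vals - vals.mean()) / sd
    return pd.DataFrame(out, index=table.index)


def _sign_align(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-|loading| entry is positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return loadings, scores


def fit_pca(table: pd.DataFrame, missing_policy: str = "drop") -> PCAModel:
    """Fit a full PCA on a standardized table.

    Rows with any missing cell are dropped (``missing_policy='drop'``, the
    only policy). All ``min(n_rows - 1, n_features)``-rank components are
    retained; explained fractions sum to 1. Deterministic: the sign
    convention removes the sign ambiguity of the SVD.
    """
    if missing_policy != "drop":
        raise ValueError(f"unsupported missing_policy {missing_policy!r}")
    complete = pd.DataFrame(table).dropna(axis=0, how="any")
    if complete.shape[0] < 2:
        raise ValueError(f"need >= 2 complete rows to fit a PCA, got {complete.shape[0]}")
    X = complete.to_numpy(dtype=np.float64)
    pca = _SKPCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    loadings, scores = _sign_align(loadings, scores)
    k = loadings.shape[1]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=list(complete.columns), columns=[f"PC{i+1}" for i in range(k)]),
        explained=np.asarray(pca.explained_variance_ratio_, dtype=np.float64),
        scores=pd.DataFrame(scores, index=complete.index, columns=[f"PC{i+1}" for i in range(k)]),
        n_used=complete.shape[0],
    )


def n_components_80(model: PCAModel, threshold: float = VARIANCE_THRESHOLD) -> int:
    """Smallest k whose cumulative explained variance reaches the threshold."""
    cum = np.cumsum(model.explained)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    if reached.size == 0:
        return int(model.n_components)
    return int(reached[0]) + 1


def multigroup_pca(tables: dict[str, pd.DataFrame]) -> tuple[dict[str, PCAModel], PCAModel]:
    """Per-group PCAs plus a pooled PCA on stacked within-group z-scores.

    Each group is z-scored within itself (so group offsets and scale do not
    dominate the pooled fit); the pooled model is fit on the stacked
    standardized rows restricted to the columns every group retains.
    Groups with fewer than 2 complete rows are skipped with a warning.
    """
    if not tables:
        raise ValueError("no groups given")
    standardized: dict[str, pd.DataFrame] = {}
    for name, tab in tables.items():
        tab = pd.DataFrame(tab)
        if tab.dropna(axis=0, how="any").shape[0] < 2:
            warnings.warn(f"group {name!r} has < 2 complete rows; skipped", stacklevel=2)
            continue
        standardized[name] = zscore(tab)
    if not standardized:
        raise ValueError("no group has enough rows for a PCA")
    shared = None
    for tab in standardized.values():
        cols = set(tab.columns)
        shared = cols if shared is None else shared & cols
    order = [c for c in next(iter(standardized.values())).columns if c in shared]
    group_models = {name: fit_pca(tab[order]) for name, tab in standardized.items()}
    stacked = pd.concat([tab[order] for tab in standardized.values()], axis=0)
    stacked.index = pd.Index(range(len(stacked)))  # group membership is not part of the pooled fit
    pooled = fit_pca(stacked)
    return group_models, pooled


def pc_cross_correlation(models: dict[str, PCAModel], k: int = 4) -> dict[tuple[str, str], pd.DataFrame]:
    """Pearson correlation between the first k PC scores of every model pair.

    Entry (i, j) of the returned matrix for pair (A, B) is the correlation
    of PC_{i+1} scores of A with PC_{j+1} scores of B over their shared
    subjects (pairwise complete); pairs with fewer than 3 shared subjects
    get NaN entries.
    """
    names = list(models)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for a in names:
        for b in names:
            ka = min(k, models[a].n_components)
            kb = min(k, models[b].n_components)
            shared = models[a].scores.index.intersection(models[b].scores.index)
            mat = np.full((ka, kb), np.nan)
            if len(shared) >= 3:
                sa = models[a].scores.loc[shared].to_numpy()
                sb = models[b].scores.loc[shared].to_numpy()
                for i in range(ka):
                    for j in range(kb):
                        mat[i, j] = scipy.stats.pearsonr(sa[:, i], sb[:, j])[0]
            out[(a, b)] = pd.DataFrame(
                mat, index=[f"PC{i+1}" for i in range(ka)], columns=[f"PC{j+1}" for j in range(kb)]
            )
    return out


def loading_similarity(
    a: pd.DataFrame | np.ndarray,
    b: pd.DataFrame | np.ndarray,
    k: int | None = None,
) -> SimilarityResult:
    """Global (single-window) SSIM between two loading matrices.

    Both matrices must cover the same feature set in the same order (a
    DataFrame pair is checked and reordered; a mismatch is an error listing
    the symmetric difference). The first ``k_used = min(k_a, k_b[, k])``
    components are compared entrywise:

        SSIM = l · cs,   l  = (2 μa μb + C1) / (μa² + μb² + C1)
                         cs = (2 cov + C2) / (σa² + σb² + C2)

    with C1 = (0.01·L)², C2 = (0.03·L)², L = 2 (loadings live in [-1, 1]).
    The luminance factor ``l`` is floored at 0 so that anti-aligned
    matrices cannot score positive through a doubly negative product, and
    the result is clamped below at 0; identical matrices score exactly 1.
    """
    if isinstance(a, pd.DataFrame) and isinstance(b, pd.DataFrame):
        sa, sb = set(a.index), set(b.index)
        if sa != sb:
            raise ValueError(f"feature sets differ: {sorted(sa ^ sb)}")
        b = b.loc[a.index]
    A = np.asarray(a, dtype=np.float64)
    B = np.asarray(b, dtype=np.float64)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"feature counts differ: {A.shape[0]} vs {B.shape[0]}")
    k_used = min(A.shape[1], B.shape[1])
    if k is not None:
        k_used = min(k_used, int(k))
    x = A[:, :k_used].ravel()
    y = B[:, :k_used].ravel()
    mu_x, mu_y = x.mean(), y.mean()
    var_x, var_y = x.var(), y.var()
    cov = ((x - mu_x) * (y - mu_y)).mean()
    lum = (2 * mu_x * mu_y + SSIM_C1) / (mu_x**2 + mu_y**2 + SSIM_C1)
    cs = (2 * cov + SSIM_C2) / (var_x + var_y + SSIM_C2)
    raw = max(lum, 0.0) * cs
    logger.debug("loading SSIM raw=%.4f (lum=%.4f, cs=%.4f, k=%d)", raw, lum, cs, k_used)
    return SimilarityResult(value=float(min(max(raw, 0.0), 1.0)), k_used=k_used)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (ties-corrected) with the chi-square p-value.

    Identical pooled values are a degenerate case: H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann–Whitney U for the first sample over the second.

    Exact enumeration when both groups have n ≤ 20 and there are no ties,
    ties-corrected normal approximation otherwise. Identical pooled
    values: U = n1·n2/2, p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    u, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(u), float(p)
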