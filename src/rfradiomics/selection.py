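"""Iterative sparse-representation (SR) feature ranking and thresholding.

The label vector (coded +1/-1) is sparsely regressed on the standardized
feature dictionary with an L1 penalty; the coefficient magnitude of a
feature measures how much it contributes to reconstructing the class
labels.  To stabilise the ranking, the fit is repeated on class-stratified
subsamples and the per-feature coefficients are averaged; features are
ranked by |average coefficient| and those below the threshold ``tal``
(default 0.004) are dropped.

Caveat: applied to the full sample before cross-validating only the
classifier (mode "paper" downstream), the selection sees the test labels —
an optimistic protocol.  The evaluation module also offers a nested mode
that re-runs selection inside each cross-validation fold.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

__all__ = [
    "SelectionResult",
    "standardize_columns",
    "sr_fit_once",
    "choose_lambda",
    "iterative_sr",
    "compare_parameter_groups",
    "DEFAULT_TAL",
]

DEFAULT_TAL = 0.004
_LAMBDA_GRID = (0.01, 0.03, 0.1, 0.3)


@dataclass
class SelectionResult:
    """Outcome of iterative SR selection."""

    coefficients: Dict[str, float]
    ranking: List[str]
    survivors: List[str]
    tal: float
    n_iter: int
    subsample_fraction: float
    lam: float
    seed: int

    def __post_init__(self) -> None:
        if sorted(self.ranking) != sorted(self.coefficients):
            raise ValueError("ranking must be a permutation of the feature names")

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "ranking": self.ranking,
            "survivors": self.survivors,
            "config": {
                "tal": self.tal,
                "n_iter": self.n_iter,
                "subsample_fraction": self.subsample_fraction,
                "lambda": self.lam,
                "seed": self.seed,
            },
        }


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Column z-scores; zero-variance columns become all-zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    ok = sd > 0
    out[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    return out


def sr_fit_once(X_sub: np.ndarray, y_sub: np.ndarray, lam: float) -> np.ndarray:
    """One L1-penalised least-squares fit of the labels on the features.

    X_sub is standardized on the subset internally; y_sub must contain both
    classes (coded to +1/-1).  Returns the per-feature coefficient vector;
    at adequate lambda most entries are exactly zero.
    """
    y = np.asarray(y_sub, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("subset contains a single class")
    if np.bincount(np.searchsorted(classes, y)).min() < 2:
        raise ValueError("need >= 2 samples per class in the subset")
    y = np.where(y == classes.max(), 1.0, -1.0)
    Xs = standardize_columns(X_sub)
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=20000, tol=1e-6)
    with warnings.catch_warnings():
        # at the smallest grid penalties the duality gap can stall slightly
        # above tol; the coefficients are converged far beyond ranking needs
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    return model.coef_.copy()


def _stratified_subsample(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(2, int(round(fraction * members.size)))
        idx.append(rng.choice(members, size=min(k, members.size), replace=False))
    return np.sort(np.concatenate(idx))


def choose_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] = _LAMBDA_GRID,
    n_rep: int = 8,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    top_k: int = 20,
) -> float:
    """Pick lambda from a small grid by subset-level ranking stability.

    For each candidate, refit on ``n_rep`` stratified subsamples and score
    the mean pairwise Jaccard overlap of the top-``top_k`` nonzero features;
    the most stable lambda wins (first on ties, so smaller penalties are
    preferred at equal stability).
    """
    y = np.asarray(y).ravel()
    best_lam, best_score = grid[0], -1.0
    for lam in grid:
        rng = np.random.default_rng(seed)
        tops = []
        for _ in range(n_rep):
            sub = _stratified_subsample(y, subsample_fraction, rng)
            coef = sr_fit_once(X[sub], y[sub], lam)
            nz = np.flatnonzero(coef != 0)
            order = nz[np.argsort(-np.abs(coef[nz]), kind="stable")]
            tops.append(frozenset(order[:top_k].tolist()))
        scores = [
            len(a & b) / len(a | b) if (a | b) else 0.0
            for a, b in itertools.combinations(tops, 2)
        ]
        score = float(np.mean(scores)) if scores else 0.0
        if score > best_score:
            best_lam, best_score = lam, score
    return best_lam


def iterative_sr(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    n_iter: int = 100,
    subsample_fraction: float = 0.8,
    lam: Optional[float] = None,
    tal: float = DEFAULT_TAL,
    seed: int = 0,
) -> SelectionResult:
    """Iterative SR: average coefficients over stratified subsample refits.

    Final coefficient = mean over iterations; ranking by |mean| descending
    with lexicographic name tie-break (deterministic); survivors are the
    features with |mean| >= tal.  Fully reproducible under ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    if np.unique(y).size != 2:
        raise ValueError("y must be binary")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{j:05d}" for j in range(p)]
    feature_names = list(feature_names)
    if len(feature_names) != p:
        raise ValueError("feature_names length must match X columns")

    if lam is None:
        lam = choose_lambda(X, y, subsample_fraction=subsample_fraction, seed=seed)

    rng = np.random.default_rng(seed)
    acc = np.zeros(p)
    for _ in range(n_iter):
        sub = (
            _stratified_subsample(y, subsample_fraction, rng)
            if subsample_fraction < 1
            else np.arange(n)
        )
        acc += sr_fit_once(X[sub], y[sub], lam)
    mean_coef = acc / n_iter

    order = sorted(range(p), key=lambda j: (-abs(mean_coef[j]), feature_names[j]))
    ranking = [feature_names[j] for j in order]
    survivors = [feature_names[j] for j in order if abs(mean_coef[j]) >= tal]
    return SelectionResult(
        coefficients={feature_names[j]: float(mean_coef[j]) for j in range(p)},
        ranking=ranking,
        survivors=survivors,
        tal=tal,
        n_iter=n_iter,
        subsample_fraction=subsample_fraction,
        lam=float(lam),
        seed=seed,
    )


def compare_parameter_groups(
    per_lesion_means: pd.DataFrame, labels: Sequence[int]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Group statistics on the per-lesion mean parametric-map values.

    Returns (anova, tukey): one-way ANOVA F and P per parameter between the
    two label groups, and a Tukey HSD pairwise table among the parameters
    themselves (values pooled over lesions, z-scored per parameter so the
    comparison is on a common scale).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size != 2 or min(np.bincount(labels)) < 2:
        raise ValueError("need two groups with >= 2 lesions each")
    rows = []
    for col in per_lesion_means.columns:
        g0 = per_lesion_means[col].to_numpy()[labels == 0]
        g1 = per_lesion_means[col].to_numpy()[labels == 1]
        if np.var(g0) == 0 and np.var(g1) == 0:
            raise ValueError(f"degenerate zero-variance input for {col}")
        f, p = stats.f_oneway(g0, g1)
        rows.append({"parameter": col, "F": float(f), "P": float(p)})
    anova = pd.DataFrame(rows)

    cols = list(per_lesion_means.columns)
    zscored = [
        stats.zscore(per_lesion_means[c].to_numpy(), ddof=0) for c in cols
    ]
    hsd = stats.tukey_hsd(*zscored)
    pairs = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            pairs.append({
                "pair": f"{cols[a]} vs {cols[b]}",
                "statistic": float(hsd.statistic[a, b]),
                "P": float(hsd.pvalue[a, b]),
            })
    return anova, pd.DataFrame(pairs)
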