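"""Classification over ranked features with leave-one-out cross-validation.

For each candidate feature count k (1..k_max) the top-k SR-ranked features
feed an RBF-kernel SVM evaluated by LOOCV: every sample is predicted by a
model trained on the remaining N-1, with feature standardisation fitted on
those N-1 only.  Metrics per k are AUC (trapezoidal, on the continuous
decision scores), accuracy, sensitivity and specificity (positive class =
label 1, hard threshold at decision score 0).  The best k maximises
accuracy, then AUC, then smallness of k.

Curves at the best k: ROC, precision-recall, and decision-curve analysis
(net benefit over threshold probabilities, with probabilities from a
Platt-style logistic link fitted on the LOOCV decision scores).  The AUC
confidence interval uses DeLong's variance estimate.

Two protocols are offered: mode "paper" ranks features once on the full
sample and cross-validates only the classifier (optimistic — the published
protocol); mode "nested" re-runs the SR selection inside every LOOCV
training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bmode import hilbert_envelope, log_compress
from .core import FeatureMap, RFFrame, WindowSpec
from .maps import dea_map, ond_map, sdsd_map
from .selection import SelectionResult, iterative_sr
from .texture import FeatureVector, assemble_model_vector, extract_350, MODEL_MAPS

__all__ = [
    "SVMConfig",
    "EvalResult",
    "loocv_predict",
    "binary_metrics",
    "trapezoid_auc",
    "delong_ci",
    "roc_prc_dca",
    "sweep_k",
    "lesion_images",
    "cohort_feature_table",
    "parameter_means",
    "run_models",
]


@dataclass(frozen=True)
class SVMConfig:
    """Gaussian-RBF SVM configuration (C=1, gamma='scale' by default)."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: object = "scale"

    def make(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)


@dataclass
class EvalResult:
    """LOOCV evaluation of one model layout (GM/DM/DOM/DOSM)."""

    model_name: str
    per_k: pd.DataFrame
    best_k: int
    scores: np.ndarray            # LOOCV decision scores at best_k
    predictions: np.ndarray       # hard labels at best_k
    roc_points: np.ndarray        # (fpr, tpr) rows
    prc_points: np.ndarray        # (recall, precision) rows
    dca_points: np.ndarray        # (threshold prob, net benefit) rows
    auc: float
    auc_ci: Tuple[float, float]
    degenerate_scores: bool = False
    selection: Optional[SelectionResult] = None

    @property
    def best_row(self) -> pd.Series:
        return self.per_k.loc[self.per_k["k"] == self.best_k].iloc[0]


def loocv_predict(
    X: np.ndarray, y: np.ndarray, svm_config: SVMConfig = SVMConfig()
) -> Tuple[np.ndarray, np.ndarray]:
    """LOOCV decision scores and hard labels.

    For each sample i the SVM (and the feature standardiser) is fitted on
    the other N-1 samples only; the held-out sample is transformed and
    scored by that model.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).ravel()
    n = y.size
    if n < 4:
        raise ValueError("LOOCV requires N >= 4")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        scaler = StandardScaler().fit(X[train])
        clf = svm_config.make().fit(scaler.transform(X[train]), y[train])
        s = float(clf.decision_function(scaler.transform(X[i : i + 1]))[0])
        scores[i] = s
        preds[i] = 1 if s > 0 else 0
    return scores, preds


def binary_metrics(y: np.ndarray, preds: np.ndarray) -> Dict[str, float]:
    """Accuracy / sensitivity / specificity with label 1 as positive."""
    y = np.asarray(y).ravel()
    preds = np.asarray(preds).ravel()
    tp = int(np.sum((preds == 1) & (y == 1)))
    tn = int(np.sum((preds == 0) & (y == 0)))
    fp = int(np.sum((preds == 1) & (y == 0)))
    fn = int(np.sum((preds == 0) & (y == 1)))
    return {
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def trapezoid_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC by the trapezoidal rule on a threshold sweep."""
    fpr, tpr, _ = roc_curve(y, scores)
    return float(np.trapezoid(tpr, fpr))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = x.size
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def delong_ci(
    scores: np.ndarray, y: np.ndarray, level: float = 0.95
) -> Tuple[float, Tuple[float, float], bool]:
    """AUC with DeLong variance-based confidence interval.

    Returns (auc, (lo, hi), degenerate) where degenerate flags a
    zero-variance (e.g. constant-score) case.
    """
    from scipy.stats import norm

    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).ravel()
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v10, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0:
        return float(auc), (float(auc), float(auc)), True
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half)), False


def roc_prc_dca(
    scores: np.ndarray,
    y: np.ndarray,
    threshold_grid: Optional[np.ndarray] = None,
) -> dict:
    """ROC, precision-recall and decision-curve points for one score set.

    Net benefit NB(pt) = TP/N - (FP/N) * pt/(1-pt), predicting positive when
    the Platt probability (logistic link fitted on the scores) reaches pt.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).ravel()
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    if threshold_grid is None:
        threshold_grid = np.linspace(0.01, 0.99, 99)

    auc, ci, degenerate = delong_ci(scores, y)
    fpr, tpr, _ = roc_curve(y, scores)
    precision, recall, _ = precision_recall_curve(y, scores)

    if np.ptp(scores) > 0:
        link = LogisticRegression(C=1e6).fit(scores[:, None], y)
        probs = link.predict_proba(scores[:, None])[:, 1]
    else:
        probs = np.full(y.size, y.mean())
    n = y.size
    nb = []
    for pt in threshold_grid:
        pred = probs >= pt
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        nb.append(tp / n - fp / n * pt / (1.0 - pt))
    return {
        "roc": np.column_stack([fpr, tpr]),
        "prc": np.column_stack([recall, precision]),
        "dca": np.column_stack([threshold_grid, nb]),
        "auc": float(np.trapezoid(tpr, fpr)),
        "auc_delong": auc,
        "auc_ci": ci,
        "degenerate": degenerate,
    }


def sweep_k(
    X_ranked: np.ndarray,
    y: np.ndarray,
    k_max: int = 50,
    svm_config: SVMConfig = SVMConfig(),
    model_name: str = "model",
    selection: Optional[SelectionResult] = None,
) -> EvalResult:
    """LOOCV metrics for the top-k ranked features, k = 1..k_max.

    X_ranked columns must already be in ranking order; k_max is clipped to
    the number of available columns.  All k share the identical LOOCV fold
    structure by construction.
    """
    X_ranked = np.asarray(X_ranked, dtype=float)
    y = np.asarray(y).ravel()
    k_max = min(k_max, X_ranked.shape[1])
    rows = []
    cached: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for k in range(1, k_max + 1):
        scores, preds = loocv_predict(X_ranked[:, :k], y, svm_config)
        cached[k] = (scores, preds)
        m = binary_metrics(y, preds)
        rows.append({
            "k": k,
            "auc": trapezoid_auc(scores, y),
            "accuracy": m["accuracy"],
            "sensitivity": m["sensitivity"],
            "specificity": m["specificity"],
        })
    per_k = pd.DataFrame(rows)
    best = per_k.sort_values(
        by=["accuracy", "auc", "k"], ascending=[False, False, True], kind="stable"
    ).iloc[0]
    best_k = int(best["k"])
    scores, preds = cached[best_k]
    curves = roc_prc_dca(scores, y)
    return EvalResult(
        model_name=model_name,
        per_k=per_k,
        best_k=best_k,
        scores=scores,
        predictions=preds,
        roc_points=curves["roc"],
        prc_points=curves["prc"],
        dca_points=curves["dca"],
        auc=curves["auc"],
        auc_ci=curves["auc_ci"],
        degenerate_scores=curves["degenerate"],
        selection=selection,
    )


# ---------------------------------------------------------------------------
# End-to-end: cohort -> images -> features -> selection -> LOOCV sweep


def lesion_images(
    frame: RFFrame,
    window: WindowSpec = WindowSpec(),
    dynamic_range_db: float = 60.0,
) -> Tuple[Dict[str, Tuple[np.ndarray, np.ndarray]], Dict[str, FeatureMap]]:
    """The four per-lesion 8-bit images: B-mode ROI + rendered DEA/OND/SDSD.

    Returns (images, maps): images maps "gray"/"dea"/"ond"/"sdsd" to
    (8-bit image, boolean mask); maps holds the raw FeatureMap objects.
    The grayscale image uses the lesion mask; the parametric maps live on
    the window grid of the ROI bounding box and use a full mask.
    """
    if frame.lesion_roi is None:
        raise ValueError("frame has no lesion ROI")
    roi = frame.lesion_roi
    fs = frame.geometry.sampling_frequency
    env = hilbert_envelope(frame)
    # the displayed grayscale image carries the acquisition's TGC curve
    # (simulated frames store the operator's depth-gain setting); the RF
    # maps below work on the raw, display-independent samples
    gain_db = frame.sim_info.get("display_gain_db")
    display_env = (
        env * (10.0 ** (np.asarray(gain_db) / 20.0))[:, None]
        if gain_db is not None
        else env
    )
    gray = log_compress(display_env, dynamic_range_db)
    roi_rf = roi.crop(frame.samples)
    roi_env = roi.crop(env)
    fmaps = {
        "dea": dea_map(roi_rf, window, fs),
        "ond": ond_map(roi_env, window),
        "sdsd": sdsd_map(roi_rf, window, fs),
    }
    images: Dict[str, Tuple[np.ndarray, np.ndarray]] = {
        "gray": (roi.crop(gray), roi.mask_in_box)
    }
    for name, fmap in fmaps.items():
        images[name] = (fmap.rendering, np.ones(fmap.values.shape, dtype=bool))
    return images, fmaps


def parameter_means(cohort: Sequence[RFFrame],
                    window: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Per-lesion mean raw DEA/OND/SDSD values (for the group ANOVA)."""
    rows = []
    for frame in cohort:
        _, fmaps = lesion_images(frame, window)
        rows.append({
            "DEA": float(fmaps["dea"].values.mean()),
            "OND": float(fmaps["ond"].values.mean()),
            "SDSD": float(fmaps["sdsd"].values.mean()),
            "label": frame.label,
        })
    return pd.DataFrame(rows)


def cohort_feature_table(
    cohort: Sequence[RFFrame],
    window: WindowSpec = WindowSpec(),
    levels: int = 32,
    dynamic_range_db: float = 60.0,
) -> Dict[str, pd.DataFrame]:
    """350-feature table per map (rows = lesions) plus a 'label' column."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    per_map_rows: Dict[str, List[Dict[str, float]]] = {
        k: [] for k in ("gray", "dea", "ond", "sdsd")
    }
    labels = []
    for frame in cohort:
        images, _ = lesion_images(frame, window, dynamic_range_db)
        labels.append(frame.label)
        for name, (img, mask) in images.items():
            fv = extract_350(img, mask, levels)
            per_map_rows[name].append(fv.as_dict())
    tables = {}
    for name, rows in per_map_rows.items():
        df = pd.DataFrame(rows)
        df["label"] = labels
        tables[name] = df
    return tables


def _model_matrix(
    tables: Dict[str, pd.DataFrame], model: str
) -> Tuple[np.ndarray, List[str], np.ndarray]:
    blocks, names = [], []
    y = tables[MODEL_MAPS[model][0]]["label"].to_numpy()
    for map_name in MODEL_MAPS[model]:
        df = tables[map_name].drop(columns="label")
        blocks.append(df.to_numpy(dtype=float))
        names.extend(f"{map_name}__{c}" for c in df.columns)
    return np.hstack(blocks), names, y.astype(int)


def run_models(
    cohort: Sequence[RFFrame],
    models: Sequence[str] = ("GM", "DM", "DOM", "DOSM"),
    mode: str = "paper",
    seed: int = 0,
    window: WindowSpec = WindowSpec(),
    k_max: int = 50,
    svm_config: SVMConfig = SVMConfig(),
    levels: int = 32,
    sr_kwargs: Optional[dict] = None,
) -> Tuple[Dict[str, EvalResult], dict]:
    """End-to-end evaluation of the requested model layouts on a cohort.

    Returns (results, extras); extras carries the per-map feature tables,
    per-model selection results, the summary table and the per-lesion
    parameter means.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if mode not in ("paper", "nested"):
        raise ValueError("mode must be 'paper' or 'nested'")
    sr_kwargs = dict(sr_kwargs or {})
    tables = cohort_feature_table(cohort, window, levels)
    results: Dict[str, EvalResult] = {}
    for model in models:
        X, names, y = _model_matrix(tables, model)
        if mode == "paper":
            sel = iterative_sr(X, y, feature_names=names, seed=seed, **sr_kwargs)
            order = [names.index(f) for f in sel.ranking]
            results[model] = sweep_k(
                X[:, order], y, k_max=k_max, svm_config=svm_config,
                model_name=model, selection=sel,
            )
        else:
            results[model] = _sweep_k_nested(
                X, y, names, k_max, svm_config, model, seed, sr_kwargs
            )
    summary = pd.DataFrame([
        {
            "model": m,
            "best_k": r.best_k,
            "auc": r.auc,
            "auc_ci_low": r.auc_ci[0],
            "auc_ci_high": r.auc_ci[1],
            "accuracy": r.best_row["accuracy"],
            "sensitivity": r.best_row["sensitivity"],
            "specificity": r.best_row["specificity"],
        }
        for m, r in results.items()
    ])
    extras = {
        "tables": tables,
        "summary": summary,
        "parameter_means": parameter_means(cohort, window),
    }
    return results, extras


def _sweep_k_nested(
    X: np.ndarray,
    y: np.ndarray,
    names: List[str],
    k_max: int,
    svm_config: SVMConfig,
    model_name: str,
    seed: int,
    sr_kwargs: dict,
) -> EvalResult:
    """Nested protocol: SR selection re-run inside each LOOCV training fold."""
    n = y.size
    k_max = min(k_max, X.shape[1])
    idx = np.arange(n)
    fold_order = []
    for i in range(n):
        train = idx != i
        sel = iterative_sr(
            X[train], y[train], feature_names=names, seed=seed, **sr_kwargs
        )
        fold_order.append([names.index(f) for f in sel.ranking])
    rows = []
    cached = {}
    for k in range(1, k_max + 1):
        scores = np.empty(n)
        preds = np.empty(n, dtype=int)
        for i in range(n):
            cols = fold_order[i][:k]
            train = idx != i
            scaler = StandardScaler().fit(X[np.ix_(train, cols)])
            clf = svm_config.make().fit(
                scaler.transform(X[np.ix_(train, cols)]), y[train]
            )
            s = float(clf.decision_function(scaler.transform(X[i : i + 1, cols]))[0])
            scores[i] = s
            preds[i] = 1 if s > 0 else 0
        cached[k] = (scores, preds)
        m = binary_metrics(y, preds)
        rows.append({
            "k": k, "auc": trapezoid_auc(scores, y),
            "accuracy": m["accuracy"], "sensitivity": m["sensitivity"],
            "specificity": m["specificity"],
        })
    per_k = pd.DataFrame(rows)
    best = per_k.sort_values(
        by=["accuracy", "auc", "k"], ascending=[False, False, True], kind="stable"
    ).iloc[0]
    best_k = int(best["k"])
    scores, preds = cached[best_k]
    curves = roc_prc_dca(scores, y)
    return EvalResult(
        model_name=model_name, per_k=per_k, best_k=best_k, scores=scores,
        predictions=preds, roc_points=curves["roc"], prc_points=curves["prc"],
        dca_points=curves["dca"], auc=curves["auc"], auc_ci=curves["auc_ci"],
        degenerate_scores=curves["degenerate"],
    )
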