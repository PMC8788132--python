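"""Response classification: linear SVM and K-means with phase binning.

Cycle responses are resampled to a fixed-length, phase-aligned feature
vector. A linear multiclass SVM (one-vs-one) with stratified 5-fold
cross-validation provides supervised ON/OFF/DUAL/NONRESPONSIVE labels;
K-means with best-of-replicates inertia, an elbow criterion on the
Calinski-Harabasz curve, and kinetics-based centroid binning provides the
unsupervised route. Traces failing the responsiveness gate are forced
NONRESPONSIVE before prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import kinetics
from .preprocess import CycleResponse, NONRESPONSIVE
from .stimulus import Phase, RampStimulus

CLASSES = ("ON", "OFF", "DUAL", "NONRESPONSIVE")

#: default feature length (samples per cycle after resampling)
FEATURE_LEN = 40


def featurize(cr: CycleResponse, L: int = FEATURE_LEN) -> np.ndarray:
    """Resample a cycle response to L phase-aligned points.

    Linear interpolation on the periodic extension; index 0 stays at the
    cycle start (luminance minimum), so features are stimulus-phase
    aligned across units and ramp durations.
    """
    z = np.asarray(cr.z, dtype=float)
    if z.size < 2:
        raise ValueError("degenerate cycle response")
    if L == z.size:
        return z.copy()
    src = np.arange(z.size + 1) / z.size  # close the cycle for interpolation
    dst = np.arange(L) / L
    return np.interp(dst, src, np.append(z, z[0]))


def featurize_all(crs: Sequence[CycleResponse], L: int = FEATURE_LEN) -> np.ndarray:
    return np.vstack([featurize(cr, L) for cr in crs])


@dataclass
class CVResult:
    """Stratified cross-validation outcome of the linear SVM."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    confusion: pd.DataFrame  # true class x predicted class counts
    classes: Tuple[str, ...]


def train_svm(
    X: np.ndarray,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> Tuple[SVC, CVResult]:
    """Train a linear multiclass SVM with stratified k-fold validation.

    Reports per-fold accuracies and the confusion matrix pooled over the
    held-out folds, then refits the model on all data. Every class must
    have at least ``folds`` examples.
    """
    labels = np.asarray(labels)
    present = [c for c in CLASSES if c in labels] + sorted(
        set(labels) - set(CLASSES)
    )
    counts = {c: int((labels == c).sum()) for c in present}
    low = [c for c, n in counts.items() if n < folds]
    if low:
        raise ValueError(f"classes with fewer than {folds} examples: {low}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, y_true, y_pred = [], [], []
    for tr_idx, te_idx in skf.split(X, labels):
        m = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        m.fit(X[tr_idx], labels[tr_idx])
        p = m.predict(X[te_idx])
        accs.append(float(np.mean(p == labels[te_idx])))
        y_true.extend(labels[te_idx])
        y_pred.extend(p)
    conf = confusion_matrix(y_true, y_pred, labels=present)
    model = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    model.fit(X, labels)
    cv = CVResult(
        fold_accuracies=np.asarray(accs),
        mean_accuracy=float(np.mean(accs)),
        confusion=pd.DataFrame(conf, index=present, columns=present),
        classes=tuple(present),
    )
    return model, cv


def predict(
    model: SVC,
    X: np.ndarray,
    gates: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Predict labels; gated-out items are forced NONRESPONSIVE."""
    y = model.predict(X).astype(object)
    if gates is not None:
        gates = np.asarray(gates)
        if gates.size != len(X):
            raise ValueError("gates length must match number of items")
        y[gates == NONRESPONSIVE] = NONRESPONSIVE
    return y.astype(str)


# ---------------------------------------------------------------------------
# unsupervised route


@dataclass
class KMeansResult:
    optimal_k: int
    cluster_labels: np.ndarray  # cluster index per item at optimal k
    class_labels: np.ndarray  # binned class per item
    centroids: np.ndarray
    ch_scores: Dict[int, float]
    centroid_classes: List[str]


def _elbow_k(ks: np.ndarray, scores: np.ndarray) -> int:
    """Knee of the score-vs-k curve: max distance from the end-point chord."""
    if ks.size == 1:
        return int(ks[0])
    if ks.size == 2:
        return int(ks[np.argmax(scores)])
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (scores - scores.min()) / max(np.ptp(scores), 1e-12)
    # perpendicular distance from the chord joining the curve's endpoints
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dy * x - dx * y + x[-1] * y[0] - y[-1] * x[0])
    return int(ks[np.argmax(dist)])


def bin_centroid(
    centroid: np.ndarray,
    stim: RampStimulus,
    min_prominence: float = kinetics.MIN_PROMINENCE,
) -> str:
    """Assign a cluster centroid to ON/OFF/DUAL/NONRESPONSIVE.

    The centroid (a resampled cycle response) is pushed through the peak
    detector. No significant peak -> NONRESPONSIVE; peaks on both ramp
    legs -> DUAL; otherwise the most prominent peak's luminance decides:
    nearer the maximum -> ON, nearer the minimum -> OFF.
    """
    cr = CycleResponse(
        z=np.asarray(centroid, dtype=float),
        rate_hz=len(centroid) / stim.period,
        period_s=stim.period,
        n_cycles_averaged=1,
    )
    peaks = kinetics.find_peaks(cr, min_prominence=min_prominence)
    if not peaks:
        return "NONRESPONSIVE"
    phases = {kinetics.peak_phase(p, stim) for p in peaks}
    if len(peaks) >= 2 and phases == {Phase.RISING, Phase.FALLING}:
        return "DUAL"
    top = max(peaks, key=lambda p: p.prominence)
    lux, _ = stim.lux_at(stim.t_start + top.t_peak % stim.period)
    mid = 0.5 * (stim.min_lux + stim.max_lux)
    return "ON" if lux >= mid else "OFF"


def kmeans_classes(
    X: np.ndarray,
    stim: RampStimulus,
    max_k: int = 8,
    replicates: int = 1000,
    seed: int = 0,
    min_prominence: float = kinetics.MIN_PROMINENCE,
) -> KMeansResult:
    """K-means over k = 2..max_k with elbow selection and class binning.

    Each k keeps the best of ``replicates`` random initializations by
    inertia; the optimal k is the knee of the Calinski-Harabasz-vs-k
    curve; clusters are then binned to classes via their centroid's peak
    phase profile.
    """
    n = len(X)
    if n <= max_k:
        raise ValueError("need more items than max_k")
    ch: Dict[int, float] = {}
    fits = {}
    for k in range(2, max_k + 1):
        km = KMeans(n_clusters=k, n_init=replicates, random_state=seed)
        lab = km.fit_predict(X)
        fits[k] = km
        ch[k] = float(calinski_harabasz_score(X, lab))
    ks = np.array(sorted(ch))
    best_k = _elbow_k(ks, np.array([ch[k] for k in ks]))
    km = fits[best_k]
    centroid_classes = [
        bin_centroid(c, stim, min_prominence) for c in km.cluster_centers_
    ]
    cluster_labels = km.labels_
    class_labels = np.array([centroid_classes[c] for c in cluster_labels])
    return KMeansResult(
        optimal_k=best_k,
        cluster_labels=cluster_labels,
        class_labels=class_labels,
        centroids=km.cluster_centers_,
        ch_scores=ch,
        centroid_classes=centroid_classes,
    )


# ---------------------------------------------------------------------------
# population summaries


def class_proportions(
    labels: Sequence[str],
    groups: Optional[Sequence[str]] = None,
    animals: Optional[Sequence[str]] = None,
    classes: Sequence[str] = ("ON", "OFF", "DUAL"),
) -> pd.DataFrame:
    """Per-group class fractions among responsive items, with SEM.

    Fractions are computed over items not labeled NONRESPONSIVE. When
    ``animals`` is given the SEM is taken across per-animal fractions;
    otherwise the SEM column is NaN.
    """
    labels = np.asarray(labels, dtype=object)
    groups = np.asarray(["all"] * len(labels) if groups is None else groups)
    animals = None if animals is None else np.asarray(animals)
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        lab = labels[sel]
        resp = lab != "NONRESPONSIVE"
        n_resp = int(resp.sum())
        if n_resp == 0:
            raise ValueError(f"group {g!r} has no responsive items")
        for c in classes:
            frac = float((lab == c).sum() / n_resp)
            sem = np.nan
            if animals is not None:
                per = []
                an = animals[sel]
                for a in pd.unique(an):
                    la = lab[an == a]
                    la = la[la != "NONRESPONSIVE"]
                    if la.size:
                        per.append((la == c).mean())
                if len(per) > 1:
                    sem = float(np.std(per, ddof=1) / np.sqrt(len(per)))
            rows.append(
                {"group": g, "class": c, "fraction": frac,
                 "n_responsive": n_resp, "sem": sem}
            )
    return pd.DataFrame(rows)
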