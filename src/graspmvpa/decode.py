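"""Pairwise maximum-margin decoding of pseudo-trial features.

All analyses share one machinery: observations are paired across the two
classes of an effect, folds leave one pair out (every fold trains on all
remaining observations and tests on the held-out pair), and a linear SVM
with per-class misclassification costs is fit per temporal window. For the
imbalanced Action contrast (twice as many grasping as knuckling
observations) the minority class carries double cost and only mixed
(one-of-each-class) pairs serve as test folds, so test sets are always
class-balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import config_context
from sklearn.svm import SVC

from .containers import (DecodingCurve, FeatureTensor, GeneralizationMatrix,
                         GRASP_ACTIONS, PseudoTrialSet, SearchlightMap)
from .montage import DEFAULT_RADIUS_MM, Montage

POOLS = ("grasping", "knuckling", "both")

#: effect -> (label column, (class0, class1))
EFFECT_CLASSES = {
    "shape": ("shape", ("pillow", "flower")),
    "color": ("color", ("red", "blue")),
    "orientation": ("orientation", ("cw", "ccw")),
    "action": ("action", ("grasp", "knuckle")),
}


def pool_mask(labels: pd.DataFrame, pool: str) -> np.ndarray:
    if pool == "grasping":
        return labels["action"].isin(GRASP_ACTIONS).to_numpy()
    if pool == "knuckling":
        return (labels["action"] == "knuckle").to_numpy()
    if pool == "both":
        return np.ones(len(labels), dtype=bool)
    raise ValueError(f"unknown pool {pool!r}")


@dataclass
class CVScheme:
    """Leave-one-pair-out cross-validation over pseudo-trial observations.

    ``folds`` holds (train_indices, test_indices) into the pseudo-trial
    axis; ``y`` maps every participating observation to its class (0/1).
    """

    effect: str
    pool: str
    y: dict[int, int]                       # global obs index -> class
    pairs: list[tuple[int, int]]
    folds: list[tuple[np.ndarray, np.ndarray]]
    class_weight: dict[int, float] = field(default_factory=lambda: {0: 1.0, 1: 1.0})
    classes: tuple[str, str] = ("class0", "class1")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def y_array(self, idx: np.ndarray) -> np.ndarray:
        return np.array([self.y[i] for i in idx])


def _leave_one_pair_out(obs: np.ndarray, test_pairs: list[tuple[int, int]]
                        ) -> list[tuple[np.ndarray, np.ndarray]]:
    folds = []
    for pair in test_pairs:
        test = np.array(pair)
        train = np.array([i for i in obs if i not in pair])
        folds.append((train, test))
    return folds


def make_cv_scheme(labels: pd.DataFrame, effect: str, pool: str,
                   seed: int = 0) -> CVScheme:
    """Build pairs, folds and class costs for one effect within one pool.

    Balanced effects (shape, color) pair the two classes within matching
    (orientation, other-feature, block) cells. Orientation and Action vary
    only between blocks, so their observations are paired across randomly
    drawn blocks (seed-controlled) within matching object cells.
    """
    if effect not in EFFECT_CLASSES:
        raise ValueError(f"unknown effect {effect!r}")
    if pool not in POOLS:
        raise ValueError(f"unknown pool {pool!r}")
    if effect == "orientation" and pool != "grasping":
        raise ValueError("orientation is defined for the grasping pool only")
    if effect == "action" and pool != "both":
        raise ValueError("action decoding uses pool='both'")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCF]))
    mask = pool_mask(labels, pool)
    sel = labels.loc[mask].copy()
    sel["_g"] = np.flatnonzero(mask)
    column, classes = EFFECT_CLASSES[effect]
    weight = {0: 1.0, 1: 1.0}

    pairs: list[tuple[int, int]] = []
    test_pairs: list[tuple[int, int]] | None = None

    if effect in ("shape", "color"):
        other = {"shape": "color", "color": "shape"}[effect]
        for _, grp in sel.fillna({"orientation": "-"}).groupby(
                ["orientation", other, "block"]):
            a = grp.loc[grp[column] == classes[0], "_g"].to_numpy()
            b = grp.loc[grp[column] == classes[1], "_g"].to_numpy()
            if len(a) != 1 or len(b) != 1:
                raise ValueError(f"cannot pair {effect} within "
                                 "(orientation, object, block) cells")
            pairs.append((int(a[0]), int(b[0])))
    elif effect == "orientation":
        if not (sel["orientation"] == "cw").any() or \
           not (sel["orientation"] == "ccw").any():
            raise ValueError("both orientations required")
        for _, grp in sel.groupby(["shape", "color"]):
            a = grp.loc[grp["orientation"] == "cw", "_g"].to_numpy()
            b = grp.loc[grp["orientation"] == "ccw", "_g"].to_numpy()
            n = min(len(a), len(b))
            a, b = rng.permutation(a)[:n], rng.permutation(b)[:n]
            pairs.extend((int(x), int(y)) for x, y in zip(a, b))
    else:  # action: imbalanced — knuckle is the minority class, double cost
        weight = {0: 1.0, 1: 2.0}
        test_pairs = []
        for _, grp in sel.groupby(["shape", "color"]):
            grasp = rng.permutation(
                grp.loc[grp["action"].isin(GRASP_ACTIONS), "_g"].to_numpy())
            knuck = rng.permutation(
                grp.loc[grp["action"] == "knuckle", "_g"].to_numpy())
            if len(grasp) == 0 or len(knuck) == 0:
                raise ValueError("both actions required in every object cell")
            n_mixed = min(len(grasp), len(knuck))
            mixed = [(int(g), int(k)) for g, k in zip(grasp[:n_mixed], knuck)]
            rest = grasp[n_mixed:]
            majority_only = [(int(rest[i]), int(rest[i + 1]))
                             for i in range(0, len(rest) - 1, 2)]
            pairs.extend(mixed + majority_only)
            test_pairs.extend(mixed)

    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for cross-validation")

    y: dict[int, int] = {}
    for _, row in sel.iterrows():
        if effect == "action":
            y[int(row["_g"])] = 1 if row["action"] == "knuckle" else 0
        else:
            y[int(row["_g"])] = classes.index(row[column])

    obs = np.array(sorted({i for p in pairs for i in p}))
    folds = _leave_one_pair_out(obs, test_pairs if test_pairs is not None else pairs)
    return CVScheme(effect=effect, pool=pool, y=y, pairs=pairs, folds=folds,
                    class_weight=weight, classes=classes)


# ---------------------------------------------------------------------------
# classifier core


def fit_decision(X_train: np.ndarray, y_train: np.ndarray,
                 class_weight: dict[int, float]) -> SVC:
    clf = SVC(kernel="linear", C=1.0, class_weight=class_weight)
    clf.fit(X_train, y_train)
    return clf


def predict(clf: SVC, X: np.ndarray) -> np.ndarray:
    """Deterministic prediction: decision value >= 0 -> class 1.

    The decision value is computed directly from the fitted hyperplane
    (linear kernel), which also keeps per-window folds cheap.
    """
    d = X @ clf.coef_.ravel() + clf.intercept_[0]
    return np.where(d >= 0, clf.classes_[1], clf.classes_[0])


# ---------------------------------------------------------------------------
# time-resolved decoding


def decode_timeresolved(features: FeatureTensor, scheme: CVScheme
                        ) -> DecodingCurve:
    """Fold-mean accuracy per temporal window."""
    n_win = features.n_windows
    acc = np.zeros(n_win)
    with config_context(assume_finite=True):
        for train, test in scheme.folds:
            y_tr, y_te = scheme.y_array(train), scheme.y_array(test)
            for w in range(n_win):
                clf = fit_decision(features.X[w, train], y_tr,
                                   scheme.class_weight)
                acc[w] += np.mean(predict(clf, features.X[w, test]) == y_te)
    acc /= len(scheme.folds)
    return DecodingCurve(accuracy=acc,
                         window_centers_ms=features.window_centers_ms,
                         effect=scheme.effect, pool=scheme.pool)


# ---------------------------------------------------------------------------
# temporal generalization


def decode_generalization(features: FeatureTensor, scheme: CVScheme,
                          t_max: float = 500.0, t_min: float = 0.0
                          ) -> GeneralizationMatrix:
    """Train at every window, test at every window within [t_min, t_max]."""
    sel = np.flatnonzero((features.window_centers_ms >= t_min) &
                         (features.window_centers_ms <= t_max))
    if sel.size == 0:
        raise ValueError("no windows inside the analysis range")
    n = sel.size
    acc = np.zeros((n, n))
    with config_context(assume_finite=True):
        for train, test in scheme.folds:
            y_tr, y_te = scheme.y_array(train), scheme.y_array(test)
            X_test_all = features.X[np.ix_(sel, test)]  # n x n_test x f
            for wi, w in enumerate(sel):
                clf = fit_decision(features.X[w, train], y_tr,
                                   scheme.class_weight)
                flat = X_test_all.reshape(n * test.size, -1)
                pred = predict(clf, flat).reshape(n, test.size)
                acc[wi] += (pred == y_te[None, :]).mean(axis=1)
    acc /= len(scheme.folds)
    return GeneralizationMatrix(accuracy=acc,
                                window_centers_ms=features.window_centers_ms[sel],
                                effect=scheme.effect, pool=scheme.pool)


# ---------------------------------------------------------------------------
# electrode searchlight


def searchlight_decode(pseudo: PseudoTrialSet, montage: Montage,
                       scheme: CVScheme, radius_mm: float = DEFAULT_RADIUS_MM,
                       bin_ms: float = 100.0) -> SearchlightMap:
    """Decode within each electrode's spatial neighborhood per 100-ms bin.

    Features for electrode e and bin b are the raw (already normalized)
    samples of all electrodes within ``radius_mm`` of e during b.
    """
    n_obs, n_el, n_samp = pseudo.traces.shape
    spb = int(round(bin_ms / 1000.0 * pseudo.sfreq))
    n_bins = n_samp // spb
    if n_bins == 0:
        raise ValueError("bin longer than the epoch")
    acc = np.zeros((n_el, n_bins))
    for e in range(n_el):
        neigh = montage.neighbors(e, radius_mm, include_self=True)
        if neigh.size == 1:
            warnings.warn(f"electrode {montage.names[e]} has no neighbor "
                          f"within {radius_mm} mm; single-electrode decoding")
        with config_context(assume_finite=True):
            for b in range(n_bins):
                sl = slice(b * spb, (b + 1) * spb)
                X = pseudo.traces[:, neigh, sl].reshape(n_obs, -1)
                total = 0.0
                for train, test in scheme.folds:
                    clf = fit_decision(X[train], scheme.y_array(train),
                                       scheme.class_weight)
                    total += np.mean(predict(clf, X[test]) ==
                                     scheme.y_array(test))
                acc[e, b] = total / len(scheme.folds)
    centers = pseudo.times[:n_bins * spb].reshape(n_bins, spb).mean(axis=1)
    return SearchlightMap(accuracy=acc, bin_centers_ms=centers,
                          electrodes=list(montage.names),
                          effect=scheme.effect, pool=scheme.pool,
                          radius_mm=radius_mm)
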