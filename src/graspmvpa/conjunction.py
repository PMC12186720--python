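"""Shape-and-Color conjunction decoding and its optimal-additive null model.

A conjunction classifier targets one object (say, red pillow) against
observations sharing only its shape (blue pillow) or only its color (red
flower). To ask whether such a classifier reflects a genuinely integrated
representation, its accuracy is compared with the best performance two
*independent* single-feature classifiers could achieve on the same test:

1. A single-feature classifier with accuracy ``p`` scores
   ``p' = 0.75 p + 0.25 (1 - p)`` on the conjunction test (it is correct on
   the minority object and the majority object differing in its feature with
   probability p, and on the remaining majority object with 1 - p).
2. Each mapped accuracy is modeled as the area under a Gaussian decision
   variable up to a boundary: ``p' = 0.5 (1 + erf((x - mu) / (sigma sqrt 2)))``
   with arbitrary mu and boundary x; solving for sigma and combining the two
   classifiers by maximum likelihood gives
   ``sigma12 = sqrt(sigma1^2 sigma2^2 / (sigma1^2 + sigma2^2))``,
   whose cumulative Gaussian is the optimal combined performance ``p12``
   (independent of the arbitrary mu, x).
   Exception: if either classifier performs at or below chance, ``p12`` is
   the maximum of the two performances and 0.5.
"""

from __future__ import annotations

import warnings
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import erf, erfinv

from .containers import DecodingCurve, FeatureTensor
from .decode import (CVScheme, decode_timeresolved, pool_mask)


# ---------------------------------------------------------------------------
# additive model


def single_feature_test_performance(p: float | np.ndarray) -> float | np.ndarray:
    """Map a single-feature accuracy onto the conjunction test: 0.75p + 0.25(1-p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("accuracy must lie in [0, 1]")
    out = 0.75 * p + 0.25 * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def _sigma_from_p(p: float, mu: float, x: float) -> float:
    """Solve the cumulative Gaussian for sigma at arbitrary (mu, x), x > mu."""
    b = erfinv(2.0 * p - 1.0)
    return (x - mu) / (np.sqrt(2.0) * b)


def optimal_additive(p1_mapped: float, p2_mapped: float,
                     mu: float = 0.0, x: float = 1.0) -> float:
    """Optimal combined performance of two mapped single-feature accuracies.

    ``mu`` and ``x`` parameterize the (arbitrary) Gaussian mean and decision
    boundary; the result is invariant to their choice. Inputs at or below
    chance trigger the exception rule (max of the inputs and 0.5); an input
    of exactly 1 saturates and returns 1 with a warning.
    """
    for p in (p1_mapped, p2_mapped):
        if not 0.0 <= p <= 1.0:
            raise ValueError("performance must lie in [0, 1]")
    if x <= mu:
        raise ValueError("decision boundary x must exceed mu")
    if p1_mapped <= 0.5 or p2_mapped <= 0.5:
        return max(p1_mapped, p2_mapped, 0.5)
    if p1_mapped >= 1.0 or p2_mapped >= 1.0:
        warnings.warn("single-feature performance saturated at 1; "
                      "combined performance is 1")
        return 1.0
    s1 = _sigma_from_p(p1_mapped, mu, x)
    s2 = _sigma_from_p(p2_mapped, mu, x)
    s12 = np.sqrt(s1 ** 2 * s2 ** 2 / (s1 ** 2 + s2 ** 2))
    return float(0.5 * (1.0 + erf((x - mu) / (s12 * np.sqrt(2.0)))))


def optimal_additive_closed_form(p1_mapped: float, p2_mapped: float) -> float:
    """Equivalent closed form: p12 = (1 + erf(sqrt(b1^2 + b2^2))) / 2.

    With b_i = erfinv(2 p_i' - 1); algebraically identical to
    :func:`optimal_additive` (the arbitrary mu, x cancel).
    """
    if p1_mapped <= 0.5 or p2_mapped <= 0.5:
        return max(p1_mapped, p2_mapped, 0.5)
    if p1_mapped >= 1.0 or p2_mapped >= 1.0:
        return 1.0
    b1 = erfinv(2.0 * p1_mapped - 1.0)
    b2 = erfinv(2.0 * p2_mapped - 1.0)
    return float(0.5 * (1.0 + erf(np.sqrt(b1 ** 2 + b2 ** 2))))


def additive_baseline(p_feature1: np.ndarray, p_feature2: np.ndarray
                      ) -> np.ndarray:
    """Element-wise optimal-additive ceiling from two raw accuracy arrays.

    Applies the single-feature mapping then the optimal combination, per
    time window (or per searchlight cell).
    """
    a = np.asarray(p_feature1, float)
    b = np.asarray(p_feature2, float)
    if a.shape != b.shape:
        raise ValueError("accuracy arrays must share a shape")
    flat = [optimal_additive_closed_form(single_feature_test_performance(x),
                                         single_feature_test_performance(y))
            for x, y in zip(a.ravel(), b.ravel())]
    return np.array(flat).reshape(a.shape)


# ---------------------------------------------------------------------------
# conjunction classifier


def make_conjunction_scheme(labels: pd.DataFrame, pool: str,
                            target: tuple[str, str], seed: int = 0) -> CVScheme:
    """CV scheme for one conjunction target (shape, color).

    The minority class is the target object itself; the majority class is
    observations sharing only the shape or only the color. Each minority
    observation is paired with one share-shape and one share-color majority
    observation (seeded assignment); each fold tests on (minority, one of
    its majority partners) and excludes the minority's *other* partner from
    training as well, so the train/test split is 33/2 for grasping and 15/2
    for knuckling under the default design. The minority class carries
    double misclassification cost and every test fold is class-balanced.
    """
    shape, color = target
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    mask = pool_mask(labels, pool)
    sel = labels.loc[mask].copy()
    sel["_g"] = np.flatnonzero(mask)

    minority = sel.loc[(sel["shape"] == shape) & (sel["color"] == color), "_g"].to_numpy()
    share_shape = sel.loc[(sel["shape"] == shape) & (sel["color"] != color), "_g"].to_numpy()
    share_color = sel.loc[(sel["shape"] != shape) & (sel["color"] == color), "_g"].to_numpy()
    if min(len(minority), len(share_shape), len(share_color)) == 0:
        raise ValueError(f"conjunction cell {target} missing from pool {pool!r}")

    # one share-shape and one share-color partner per minority observation
    ss = rng.permutation(share_shape)
    sc = rng.permutation(share_color)
    n = len(minority)
    if len(ss) < n or len(sc) < n:
        raise ValueError("not enough majority observations to pair")
    partners = {int(m): (int(ss[i]), int(sc[i])) for i, m in enumerate(minority)}

    obs = np.concatenate([minority, share_shape, share_color])
    y = {int(i): 0 for i in np.concatenate([share_shape, share_color])}
    y.update({int(i): 1 for i in minority})

    folds, pairs = [], []
    for m, (a, b) in partners.items():
        pairs.append((m, a))
        pairs.append((m, b))
        for test_major, excluded in ((a, b), (b, a)):
            train = np.array([i for i in obs if i not in (m, test_major, excluded)])
            folds.append((train, np.array([m, test_major])))
    return CVScheme(effect=f"conjunction:{shape}-{color}", pool=pool, y=y,
                    pairs=pairs, folds=folds, class_weight={0: 1.0, 1: 2.0},
                    classes=("single-feature", "both-features"))


def conjunction_decode(features: FeatureTensor, pool: str,
                       seed: int = 0) -> DecodingCurve:
    """Average conjunction accuracy over the four shape x color targets."""
    shapes = sorted(features.labels["shape"].unique())
    colors = sorted(features.labels["color"].unique())
    curves = []
    for target in product(shapes, colors):
        scheme = make_conjunction_scheme(features.labels, pool, target, seed=seed)
        curves.append(decode_timeresolved(features, scheme).accuracy)
    return DecodingCurve(accuracy=np.mean(curves, axis=0),
                         window_centers_ms=features.window_centers_ms,
                         effect="conjunction", pool=pool)
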