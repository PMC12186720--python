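"""Group-level statistics for decoding results.

Two procedures:

* Cluster-based sign-permutation tests: one-sample t statistics of
  (accuracy - chance) across subjects, point-wise thresholded at the 95th
  percentile of their sign-flip permutation distribution, with family-wise
  correction by the permutation distribution of the maximum cluster size
  (clusters are runs of consecutive time windows, or spatially connected
  electrode sets for searchlight maps). One-tailed throughout.

* ROI bootstrap tests on the temporal-generalization plane: mean accuracy
  differences between two pools (e.g., grasping - knuckling) within
  geometric regions of interest, with one-tailed 95% bootstrap confidence
  intervals over subjects; a region counts as significant when its
  difference is more positive than the baseline region's with
  non-overlapping one-tailed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components


# ---------------------------------------------------------------------------
# cluster-based sign-permutation tests


@dataclass
class Cluster:
    members: np.ndarray          # window indices or electrode indices
    size: int
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    point_threshold: np.ndarray  # per-point t threshold (95th perm percentile)
    t_obs: np.ndarray
    max_size_null: np.ndarray    # permutation distribution of max cluster size
    size_threshold: float        # smallest size with corrected p <= alpha
    n_permutations: int
    alpha: float
    tail: str = "greater"

    @property
    def significant_mask(self) -> np.ndarray:
        mask = np.zeros_like(self.t_obs, dtype=bool)
        for c in self.clusters:
            if c.significant:
                mask[c.members] = True
        return mask


def _t_onesample(x: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0; zero-variance points map to 0 t."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, np.sign(m) * 1e12)


def _runs(mask: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of consecutive True entries."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return np.split(idx, breaks + 1)


def _component_sets(mask: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of the supra-threshold electrode subgraph."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[np.ix_(idx, idx)]
    n_comp, lab = connected_components(sparse.csr_matrix(sub), directed=False)
    return [idx[lab == k] for k in range(n_comp)]


def _max_run_lengths(supra: np.ndarray) -> np.ndarray:
    """Per-row maximal run of True in a (n_perm, n_points) boolean array."""
    out = np.zeros(supra.shape[0])
    run = np.zeros(supra.shape[0])
    for j in range(supra.shape[1]):
        run = (run + 1) * supra[:, j]
        out = np.maximum(out, run)
    return out


def _cluster_permutation(values: np.ndarray, chance: float, n_perm: int,
                         alpha: float, seed: int | None,
                         clusterer, max_size_fn=None) -> ClusterResult:
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable percentiles")
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a subjects x points array with >= 2 subjects")
    rng = np.random.default_rng(seed)
    x = values - chance
    n_sub, n_pt = x.shape

    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    # sign flips leave per-point sums of squares unchanged, so the whole
    # permutation t ensemble reduces to one matrix product
    ssq = (x ** 2).sum(axis=0)
    m_perm = flips @ x / n_sub
    var_perm = np.maximum(ssq[None, :] / n_sub - m_perm ** 2, 0.0) * n_sub / (n_sub - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m_perm / np.sqrt(var_perm / n_sub)
    t_perm = np.where(np.isfinite(t_perm), t_perm, np.sign(m_perm) * 1e12)
    point_thr = np.percentile(t_perm, 100 * (1 - alpha), axis=0)

    t_obs = _t_onesample(x)
    obs_clusters = clusterer(t_obs > point_thr)

    if max_size_fn is not None:
        max_sizes = max_size_fn(t_perm > point_thr[None, :])
    else:
        max_sizes = np.zeros(n_perm)
        for i in range(n_perm):
            sizes = [len(c) for c in clusterer(t_perm[i] > point_thr)]
            max_sizes[i] = max(sizes) if sizes else 0
    # cluster sizes are integers, so the naive "size >= 95th percentile"
    # rule over-rejects whenever the null piles mass on the percentile
    # value; the corrected p-value P(max null size >= observed) <= alpha is
    # the exact discrete equivalent. size_threshold is the smallest size
    # that clears it.
    candidates = np.arange(1, values.shape[1] + 1)
    attained = [(max_sizes >= s).mean() <= alpha for s in candidates]
    size_thr = float(candidates[np.argmax(attained)]) if any(attained) \
        else float(values.shape[1] + 1)

    clusters = [Cluster(members=c, size=len(c),
                        significant=(max_sizes >= len(c)).mean() <= alpha)
                for c in obs_clusters]
    return ClusterResult(clusters=clusters, point_threshold=point_thr,
                         t_obs=t_obs, max_size_null=max_sizes,
                         size_threshold=float(size_thr),
                         n_permutations=n_perm, alpha=alpha)


def cluster_test_time(accuracies: np.ndarray, chance: float = 0.5,
                      n_perm: int = 10_000, alpha: float = 0.05,
                      seed: int | None = None) -> ClusterResult:
    """Temporal cluster test on a subjects x windows accuracy array.

    Clusters are maximal runs of consecutive supra-threshold windows;
    one-tailed against accuracies above ``chance``.
    """
    accuracies = np.asarray(accuracies, float)
    return _cluster_permutation(accuracies, chance, n_perm, alpha, seed,
                                _runs, max_size_fn=_max_run_lengths)


def cluster_test_spatial(maps: np.ndarray, adjacency: np.ndarray,
                         chance: float = 0.5, n_perm: int = 10_000,
                         alpha: float = 0.05,
                         seed: int | None = None) -> list[ClusterResult]:
    """Spatial cluster tests, one per time bin.

    ``maps`` is subjects x electrodes x bins; ``adjacency`` a boolean
    electrode neighbor matrix. Each bin is tested independently; clusters
    are connected sets of supra-threshold electrodes (an edgeless adjacency
    degenerates to single-electrode clusters).
    """
    maps = np.asarray(maps, float)
    if maps.ndim != 3:
        raise ValueError("maps must be subjects x electrodes x bins")
    adjacency = np.asarray(adjacency, bool)
    results = []
    ss = np.random.SeedSequence(seed)
    for b, child in enumerate(ss.spawn(maps.shape[2])):
        results.append(_cluster_permutation(
            maps[:, :, b], chance, n_perm, alpha,
            child.generate_state(1)[0] % (2 ** 31),
            lambda m: _component_sets(m, adjacency)))
    return results


# ---------------------------------------------------------------------------
# generalization-plane ROIs


@dataclass
class ROISpec:
    """A geometric region of the train-time x test-time plane (ms).

    ``mask(train_ms, test_ms)`` evaluates membership on window centers.
    Default geometry: baseline = first 50 ms x first 50 ms; diagonal =
    |train - test| <= 30 ms within 100-500 ms; arms = early train x late
    test (plus transpose), excluding the diagonal band; triangular = the
    remaining off-diagonal plane within 100-500 ms; arms_early = the arms
    shifted 50 ms earlier (90-160 ms anchor).
    """

    name: str
    kind: str                                      # box | diagonal | arms | triangular
    t_range: tuple[float, float] = (100.0, 500.0)
    diag_halfwidth_ms: float = 30.0
    train_band: tuple[float, float] = (140.0, 210.0)
    test_band: tuple[float, float] = (270.0, 500.0)
    exclude: tuple["ROISpec", ...] = field(default_factory=tuple)

    def mask(self, train_ms: np.ndarray, test_ms: np.ndarray) -> np.ndarray:
        tr = np.asarray(train_ms)[:, None]
        te = np.asarray(test_ms)[None, :]
        lo, hi = self.t_range
        if self.kind == "box":
            m = (tr >= lo) & (tr <= hi) & (te >= lo) & (te <= hi)
        elif self.kind == "diagonal":
            m = ((np.abs(tr - te) <= self.diag_halfwidth_ms) &
                 (tr >= lo) & (tr <= hi) & (te >= lo) & (te <= hi))
        elif self.kind == "arms":
            a = ((tr >= self.train_band[0]) & (tr <= self.train_band[1]) &
                 (te >= self.test_band[0]) & (te <= self.test_band[1]))
            m = (a | a.T) & (np.abs(tr - te) > self.diag_halfwidth_ms)
        elif self.kind == "triangular":
            m = ((tr >= lo) & (tr <= hi) & (te >= lo) & (te <= hi) &
                 (np.abs(tr - te) > self.diag_halfwidth_ms))
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        for other in self.exclude:
            m = m & ~other.mask(train_ms, test_ms)
        return m


def default_rois() -> dict[str, ROISpec]:
    baseline = ROISpec("baseline", "box", t_range=(0.0, 50.0))
    diagonal = ROISpec("diagonal", "diagonal")
    arms = ROISpec("arms", "arms")
    triangular = ROISpec("triangular", "triangular", exclude=(arms,))
    arms_early = ROISpec("arms_early", "arms",
                         train_band=(90.0, 160.0), test_band=(220.0, 500.0))
    return {"baseline": baseline, "diagonal": diagonal, "arms": arms,
            "triangular": triangular, "arms_early": arms_early}


@dataclass
class ROIResult:
    differences: dict[str, float]                  # mean pool-A minus pool-B
    ci_lower: dict[str, float]                     # one-tailed 5th percentile
    ci_upper: dict[str, float]                     # one-tailed 95th percentile
    significant: dict[str, bool]                   # vs the baseline ROI
    n_bootstrap: int
    baseline_name: str = "baseline"


def roi_difference_test(gmats_a: np.ndarray, gmats_b: np.ndarray,
                        window_centers_ms: np.ndarray,
                        rois: dict[str, ROISpec] | None = None,
                        n_boot: int = 10_000,
                        baseline_name: str = "baseline",
                        seed: int | None = None) -> ROIResult:
    """Bootstrap ROI differences between two pools' generalization matrices.

    ``gmats_a``/``gmats_b`` are subjects x train x test accuracy stacks on a
    shared window axis. Per subject and ROI the mean accuracy difference
    (A - B) is formed; bootstrapping subjects with replacement yields
    one-tailed 95% intervals. A non-baseline ROI is significant when its
    mean difference exceeds the baseline's and its lower bound clears the
    baseline's upper bound.
    """
    rois = rois if rois is not None else default_rois()
    a = np.asarray(gmats_a, float)
    b = np.asarray(gmats_b, float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("pools must be equal-shaped subjects x train x test")
    centers = np.asarray(window_centers_ms, float)
    if a.shape[1] != centers.size or a.shape[2] != centers.size:
        raise ValueError("window axis does not match the matrices")
    if baseline_name not in rois:
        raise ValueError(f"baseline ROI {baseline_name!r} missing")

    per_subject = {}
    for name, roi in rois.items():
        m = roi.mask(centers, centers)
        if not m.any():
            raise ValueError(f"ROI {name!r} covers no cells of the matrix")
        per_subject[name] = a[:, m].mean(axis=1) - b[:, m].mean(axis=1)

    n_sub = a.shape[0]
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_sub, size=(n_boot, n_sub))
    diff, lo, hi = {}, {}, {}
    for name, d in per_subject.items():
        boot = d[draws].mean(axis=1)
        diff[name] = float(d.mean())
        lo[name] = float(np.percentile(boot, 5))
        hi[name] = float(np.percentile(boot, 95))
    sig = {}
    for name in rois:
        if name == baseline_name:
            sig[name] = False
        else:
            sig[name] = (diff[name] > diff[baseline_name] and
                         lo[name] > hi[baseline_name])
    return ROIResult(differences=diff, ci_lower=lo, ci_upper=hi,
                     significant=sig, n_bootstrap=n_boot,
                     baseline_name=baseline_name)


def classify_dynamics(result: ROIResult) -> str:
    """Label the pool difference by its generalization geometry.

    Triangular significance indicates a sustained code (with or without
    arms); otherwise arms significance indicates reactivation; otherwise
    diagonal-only significance indicates a chained code.
    """
    if result.significant.get("triangular"):
        return "sustained"
    if result.significant.get("arms"):
        return "reactivated"
    if result.significant.get("diagonal"):
        return "chained"
    return "none"
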