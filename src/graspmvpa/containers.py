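"""Core in-memory containers shared across the pipeline.

Everything downstream of the simulator speaks in terms of three arrays:

* :class:`EpochSet` — single-trial data, ``trials x electrodes x samples``,
  with a per-trial label table. Used both for voltage epochs and for
  narrow-band Hilbert power (the ``units`` field tells them apart).
* :class:`PseudoTrialSet` — condition-by-block averages ("pseudo-trials"),
  the observation unit fed to classifiers, with a normalization state flag.
* :class:`FeatureTensor` — pseudo-trials windowed into consecutive
  spatiotemporal feature vectors (``windows x pseudo-trials x features``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: label columns every trial table must carry
TRIAL_COLUMNS = ("block", "action", "orientation", "shape", "color",
                 "valid", "reaction_time")

GRASP_ACTIONS = ("grasp_cw", "grasp_ccw")
ACTIONS = GRASP_ACTIONS + ("knuckle",)
SHAPES = ("pillow", "flower")
COLORS = ("red", "blue")
ORIENTATIONS = ("cw", "ccw")


def _check_labels(labels: pd.DataFrame, n: int, required: tuple[str, ...]) -> None:
    if len(labels) != n:
        raise ValueError(f"label table has {len(labels)} rows for {n} observations")
    missing = [c for c in required if c not in labels.columns]
    if missing:
        raise ValueError(f"label table missing columns {missing}")


@dataclass
class EpochSet:
    """Labeled epoched data for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_electrodes, n_samples)
        Signal in microvolts (or squared-amplitude power units after the
        Hilbert band-power transform).
    times : ndarray, shape (n_samples,)
        Epoch time axis in milliseconds relative to stimulus (Preview) onset.
    labels : DataFrame
        One row per trial; see :data:`TRIAL_COLUMNS`. ``orientation`` is
        defined only for grasp trials (``None``/NaN for knuckling).
    """

    subject: int
    data: np.ndarray
    times: np.ndarray
    labels: pd.DataFrame
    sfreq: float
    montage: "object | None" = None
    units: str = "uV"
    band: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x electrodes x samples")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length does not match data")
        _check_labels(self.labels, self.data.shape[0], TRIAL_COLUMNS)
        grasp = self.labels["action"].isin(GRASP_ACTIONS)
        if self.labels.loc[grasp, "orientation"].isna().any():
            raise ValueError("grasp trials must carry an orientation label")
        if self.labels.loc[~grasp, "orientation"].notna().any():
            raise ValueError("orientation is defined only for grasp trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return replace(self, data=self.data.copy(),
                       labels=self.labels.copy(), times=self.times.copy())

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by a boolean or index mask (labels re-indexed)."""
        return replace(self, data=self.data[mask],
                       labels=self.labels.iloc[mask].reset_index(drop=True))


#: normalization states a PseudoTrialSet moves through, in pipeline order
PSEUDO_STATES = ("raw", "whitened", "z_winsorized")

PSEUDO_COLUMNS = ("block", "action", "orientation", "shape", "color")


@dataclass
class PseudoTrialSet:
    """Condition-by-block averaged traces: the classifier observation unit."""

    subject: int
    traces: np.ndarray          # pseudo-trials x electrodes x samples
    times: np.ndarray
    labels: pd.DataFrame        # block, action, orientation, shape, color
    sfreq: float
    state: str = "raw"
    units: str = "uV"
    band: str | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.traces.ndim != 3:
            raise ValueError("traces must be pseudo-trials x electrodes x samples")
        if self.state not in PSEUDO_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        _check_labels(self.labels, self.traces.shape[0], PSEUDO_COLUMNS)

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    def copy(self) -> "PseudoTrialSet":
        return replace(self, traces=self.traces.copy(), labels=self.labels.copy())


@dataclass
class FeatureTensor:
    """Windowed spatiotemporal features.

    ``X[w, i]`` is the feature vector of pseudo-trial ``i`` in temporal
    window ``w``: all electrodes' consecutive samples concatenated
    (64 electrodes x 5 bins = 320 features under the default design).
    """

    X: np.ndarray               # windows x pseudo-trials x features
    window_centers_ms: np.ndarray
    labels: pd.DataFrame
    bins_per_window: int
    n_electrodes: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 3:
            raise ValueError("X must be windows x pseudo-trials x features")
        if self.X.shape[2] != self.n_electrodes * self.bins_per_window:
            raise ValueError("feature dimension != electrodes * bins_per_window")
        _check_labels(self.labels, self.X.shape[1], PSEUDO_COLUMNS)

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]


@dataclass
class DecodingCurve:
    """Per-subject time-resolved accuracy for one effect/pool."""

    accuracy: np.ndarray        # (n_windows,)
    window_centers_ms: np.ndarray
    effect: str
    pool: str
    subject: int | None = None
    chance: float = 0.5
    band: str | None = None

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time accuracy grid for one subject."""

    accuracy: np.ndarray        # (n_train, n_test), square on analysis range
    window_centers_ms: np.ndarray
    effect: str
    pool: str
    subject: int | None = None

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        if self.accuracy.shape[0] != self.accuracy.shape[1]:
            raise ValueError("generalization matrix must be square")

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)


@dataclass
class SearchlightMap:
    """Electrode x 100-ms-bin accuracy map for one subject."""

    accuracy: np.ndarray        # (n_electrodes, n_bins)
    bin_centers_ms: np.ndarray
    electrodes: list[str] = field(default_factory=list)
    effect: str = ""
    pool: str = ""
    subject: int | None = None
    radius_mm: float = 50.0

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
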