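"""Epoch-level cleaning: bad electrodes, average reference, trial rejection.

Order of operations is fixed: (1) detect electrodes whose median correlation
with their spatial neighbors falls below threshold, (2) replace them by an
inverse-distance-weighted average of their good neighbors, (3) re-reference
every sample to the average of all electrodes, (4) drop trials flagged
invalid or with out-of-bounds reaction times.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .containers import EpochSet
from .montage import DEFAULT_RADIUS_MM, Montage


@dataclass
class CleaningReport:
    interpolated: list[str] = field(default_factory=list)
    rejected: dict[int, str] = field(default_factory=dict)   # trial idx -> reason
    n_trials_in: int = 0
    fraction_removed: float = 0.0

    def to_json(self, path) -> None:
        d = asdict(self)
        d["rejected"] = {str(k): v for k, v in self.rejected.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def neighbor_correlations(epochs: EpochSet, montage: Montage,
                          radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
    """Median Pearson correlation of each electrode with its neighbors.

    Computed broadband over all epochs concatenated in time; the median is
    robust to a single dead neighbor dragging down an otherwise good
    channel. Electrodes with no neighbor at the given radius get NaN.
    """
    flat = epochs.data.transpose(1, 0, 2).reshape(epochs.n_electrodes, -1)
    corr = np.corrcoef(flat)
    out = np.full(epochs.n_electrodes, np.nan)
    for i in range(epochs.n_electrodes):
        nb = montage.neighbors(i, radius_mm)
        if nb.size:
            out[i] = np.nanmedian(corr[i, nb])
    return out


def _interpolate(data: np.ndarray, bad: np.ndarray, montage: Montage,
                 radius_mm: float) -> list[str]:
    """Replace bad channels in-place by IDW averages of good neighbors."""
    names = []
    good = ~bad
    for i in np.flatnonzero(bad):
        nb = montage.neighbors(i, radius_mm)
        nb = nb[good[nb]]
        if nb.size == 0:                       # widen until a good donor exists
            order = np.argsort(montage.distances_mm[i])
            nb = np.array([j for j in order if good[j] and j != i][:3])
        w = 1.0 / np.maximum(montage.distances_mm[i, nb], 1e-9)
        w /= w.sum()
        data[:, i, :] = np.einsum("n,tns->ts", w, data[:, nb, :])
        names.append(montage.names[i])
    return names


def average_reference(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=1, keepdims=True)


def bandpass_epochs(epochs: EpochSet, l_freq: float = 0.1,
                    h_freq: float = 40.0, order: int = 2) -> EpochSet:
    """Optional zero-phase Butterworth band-pass applied per epoch.

    A stand-in for the acquisition band-pass that the original recordings
    received on continuous data; off by default since the simulator's epochs
    are already band-limited by construction.
    """
    sos = butter(order, [l_freq, h_freq], btype="bandpass", output="sos",
                 fs=epochs.sfreq)
    out = epochs.copy()
    out.data = sosfiltfilt(sos, out.data, axis=-1)
    return out


def clean_epochs(epochs: EpochSet, montage: Montage | None = None,
                 corr_threshold: float = 0.6,
                 rt_bounds: tuple[float, float] = (100.0, 1000.0),
                 radius_mm: float = DEFAULT_RADIUS_MM,
                 ) -> tuple[EpochSet, CleaningReport]:
    """Clean one subject's epochs; returns the cleaned set and a report.

    Trials flagged invalid are rejected with reason ``"invalid"``; a valid
    trial whose reaction time falls outside ``rt_bounds`` is rejected with
    reason ``"rt_out_of_bounds"`` (one primary reason per trial, invalidity
    taking precedence).
    """
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    montage = montage or epochs.montage
    if montage is None or len(montage) != epochs.n_electrodes:
        raise ValueError("montage must cover all electrodes")

    report = CleaningReport(n_trials_in=epochs.n_trials)
    out = epochs.copy()

    nc = neighbor_correlations(out, montage, radius_mm)
    bad = nc < corr_threshold
    if bad.all():
        raise ValueError("all electrodes fail the neighbor-correlation rule; "
                         "input looks corrupt")
    if bad.any():
        report.interpolated = _interpolate(out.data, bad, montage, radius_mm)

    out.data = average_reference(out.data)

    lab = out.labels
    reasons = {}
    for i in range(len(lab)):
        if not bool(lab["valid"].iloc[i]):
            reasons[i] = "invalid"
        elif not (rt_bounds[0] <= lab["reaction_time"].iloc[i] <= rt_bounds[1]):
            reasons[i] = "rt_out_of_bounds"
    report.rejected = reasons
    report.fraction_removed = len(reasons) / epochs.n_trials
    keep = np.array([i not in reasons for i in range(len(lab))])
    out = out.select(keep)
    if out.n_trials == 0:
        warnings.warn("all trials rejected")
    return out, report
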