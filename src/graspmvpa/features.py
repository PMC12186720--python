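"""Classifier-ready features from cleaned epochs.

The ERP path is: pseudo-trial averaging -> multivariate noise normalization
(whitening by the inverse square root of a condition- and time-averaged
electrode covariance) -> per-trace z-scoring with +-3 SD winsorization ->
non-overlapping 5-bin spatiotemporal windows (~10 ms at 512 Hz, 64 x 5 = 320
features). The spectral path prepends a narrow-band Hilbert power transform
to the same chain.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firls, hilbert

from .containers import EpochSet, FeatureTensor, PseudoTrialSet

# condition = full crossing of the design labels
CONDITION_COLS = ["action", "orientation", "shape", "color"]


# ---------------------------------------------------------------------------
# pseudo-trial averaging


def average_pseudotrials(epochs: EpochSet) -> PseudoTrialSet:
    """Average same-object epochs within each block into one trace.

    Up to ``reps_per_object`` epochs of the same object within one action
    block are averaged into a single pseudo-trial, giving one trace per
    (block, object) cell — six traces per condition per action pool under
    the default design. Cells left empty by trial rejection are omitted
    with a warning.
    """
    lab = epochs.labels
    rows, traces = [], []
    for (block, shape, color), idx in sorted(
            lab.groupby(["block", "shape", "color"], dropna=False).groups.items()):
        idx = np.asarray(idx)
        traces.append(epochs.data[idx].mean(axis=0))
        first = lab.iloc[idx[0]]
        rows.append((block, first["action"], first["orientation"], shape, color))
    expected = lab["block"].nunique() * 4
    if len(rows) < expected:
        warnings.warn(f"{expected - len(rows)} (block, object) cells had no "
                      "surviving epochs; traces omitted")
    labels = pd.DataFrame(rows, columns=["block", "action", "orientation",
                                         "shape", "color"])
    return PseudoTrialSet(subject=epochs.subject, traces=np.array(traces),
                          times=epochs.times, labels=labels,
                          sfreq=epochs.sfreq, state="raw",
                          units=epochs.units, band=epochs.band)


# ---------------------------------------------------------------------------
# multivariate noise normalization


def _condition_groups(labels: pd.DataFrame):
    return labels.fillna({"orientation": "-"}).groupby(CONDITION_COLS).groups


def noise_normalize(pseudo: PseudoTrialSet,
                    shrinkage: float = 0.05) -> PseudoTrialSet:
    """Whiten traces by the inverse square root of the noise covariance.

    The electrode covariance is estimated at every time point within each
    condition (across that condition's traces), averaged over time points
    and conditions into a single matrix, diagonally loaded by ``shrinkage``,
    and its inverse square root applied to every sample of every trace —
    one common whitening transform for all conditions.
    """
    if pseudo.state != "raw":
        raise ValueError(f"expected raw traces, got state {pseudo.state!r}")
    groups = [np.asarray(ix) for ix in _condition_groups(pseudo.labels).values()
              if len(ix) >= 2]
    if not groups:
        raise ValueError("no condition has >= 2 traces; covariance undefined")
    p = pseudo.traces.shape[1]
    sigma = np.zeros((p, p))
    for idx in groups:
        X = pseudo.traces[idx]                       # k x p x T
        Xc = X - X.mean(axis=0, keepdims=True)
        # per-time-point covariance, then mean over time
        sigma += np.einsum("kpt,kqt->pq", Xc, Xc) / ((len(idx) - 1) * X.shape[2])
    sigma /= len(groups)
    lam = shrinkage * np.trace(sigma) / p
    sigma_reg = (1.0 - shrinkage) * sigma + lam * np.eye(p)
    evals, evecs = np.linalg.eigh(sigma_reg)
    W = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T
    out = pseudo.copy()
    out.traces = np.einsum("pq,tqs->tps", W, pseudo.traces)
    out.state = "whitened"
    return out


# ---------------------------------------------------------------------------
# z-score + winsorize


def z_winsorize(pseudo: PseudoTrialSet, limit: float = 3.0) -> PseudoTrialSet:
    """Standardize each trace over its time x electrode values, clip at +-limit."""
    if pseudo.state != "whitened":
        raise ValueError(f"expected whitened traces, got state {pseudo.state!r}")
    out = pseudo.copy()
    mu = out.traces.mean(axis=(1, 2), keepdims=True)
    sd = out.traces.std(axis=(1, 2), keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant trace: z-score undefined")
    out.traces = np.clip((out.traces - mu) / sd, -limit, limit)
    out.state = "z_winsorized"
    return out


# ---------------------------------------------------------------------------
# spatiotemporal windows


def window_features(pseudo: PseudoTrialSet,
                    bins_per_window: int = 5) -> FeatureTensor:
    """Cut traces into consecutive non-overlapping windows of samples.

    Each window's feature vector concatenates every electrode's
    ``bins_per_window`` consecutive samples; a final partial window is
    discarded.
    """
    n_tr, n_el, n_samp = pseudo.traces.shape
    if bins_per_window > n_samp:
        raise ValueError("bins_per_window exceeds trace length")
    n_win = n_samp // bins_per_window
    trimmed = pseudo.traces[:, :, :n_win * bins_per_window]
    # windows x trials x (electrodes*bins)
    X = (trimmed.reshape(n_tr, n_el, n_win, bins_per_window)
                .transpose(2, 0, 1, 3)
                .reshape(n_win, n_tr, n_el * bins_per_window))
    centers = pseudo.times[:n_win * bins_per_window] \
        .reshape(n_win, bins_per_window).mean(axis=1)
    return FeatureTensor(X=X, window_centers_ms=centers, labels=pseudo.labels,
                         bins_per_window=bins_per_window, n_electrodes=n_el)


# ---------------------------------------------------------------------------
# narrow-band Hilbert power

#: canonical frequency bands (Hz)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (3.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (15.0, 25.0),
    "gamma": (30.0, 40.0),
}


def _fir_bandpass(band: tuple[float, float], sfreq: float,
                  n_samples: int) -> np.ndarray:
    """Least-squares FIR band-pass taps for forward-backward filtering.

    The transition bandwidth is 1 Hz or 25% of the band edge, whichever is
    larger. Tap count targets three cycles of the low edge but is capped so
    that ``filtfilt``'s default padding fits the epoch.
    """
    lo, hi = band
    nyq = sfreq / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} invalid for sampling rate {sfreq}")
    tw_lo = max(1.0, 0.25 * lo)
    tw_hi = max(1.0, 0.25 * hi)
    stop_lo = max(lo - tw_lo, 0.5 * lo)
    stop_hi = min(hi + tw_hi, hi + 0.5 * (nyq - hi))
    numtaps = int(3 * sfreq / lo)
    cap = (n_samples - 2) // 3
    numtaps = min(numtaps, cap)
    if numtaps % 2 == 0:
        numtaps -= 1
    if numtaps < 9:
        raise ValueError("epoch too short for band-pass filtering")
    bands = [0.0, stop_lo, lo, hi, stop_hi, nyq]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return firls(numtaps, bands, desired, fs=sfreq)


def band_power(epochs: EpochSet, band: str | tuple[float, float]) -> EpochSet:
    """Narrow-band instantaneous power via zero-phase FIR + Hilbert transform.

    Per trial and electrode: two-way (forward-backward) least-squares FIR
    band-pass at the band edges, analytic signal by Hilbert transform,
    squared magnitude. The result is an :class:`EpochSet` in power units
    that feeds the same pseudo-trial/normalization chain as voltages.
    """
    name = band if isinstance(band, str) else None
    edges = BANDS[band] if isinstance(band, str) else tuple(band)
    taps = _fir_bandpass(edges, epochs.sfreq, epochs.n_samples)
    out = epochs.copy()
    narrow = filtfilt(taps, [1.0], out.data, axis=-1)
    analytic = hilbert(narrow, axis=-1)
    out.data = np.abs(analytic) ** 2
    out.units = "power"
    out.band = name or f"{edges[0]:g}-{edges[1]:g}Hz"
    return out
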