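"""HDF5 / CSV persistence for the pipeline's containers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .containers import EpochSet, PseudoTrialSet
from .montage import Montage

_LABEL_COLS = ["block", "action", "orientation", "shape", "color",
               "valid", "reaction_time"]
_PSEUDO_COLS = ["block", "action", "orientation", "shape", "color"]


def _write_labels(group: h5py.Group, labels: pd.DataFrame, cols) -> None:
    sub = group.create_group("labels")
    for c in cols:
        if c not in labels.columns:
            continue
        v = labels[c]
        if v.dtype == object or str(v.dtype).startswith("str"):
            enc = np.array(["" if x is None or (isinstance(x, float) and np.isnan(x))
                            else str(x) for x in v], dtype="S16")
            sub.create_dataset(c, data=enc)
        else:
            sub.create_dataset(c, data=v.to_numpy())


def _read_labels(group: h5py.Group) -> pd.DataFrame:
    out = {}
    for c, ds in group.items():
        arr = ds[()]
        if arr.dtype.kind == "S":
            dec = np.array([x.decode() for x in arr], dtype=object)
            dec[dec == ""] = None
            out[c] = dec
        else:
            out[c] = arr
    return pd.DataFrame(out)


def _write_montage(group: h5py.Group, montage: Montage) -> None:
    g = group.create_group("montage")
    g.create_dataset("names", data=np.array(montage.names, dtype="S16"))
    g.create_dataset("positions_mm", data=montage.positions_mm)


def _read_montage(group: h5py.Group) -> Montage:
    names = [n.decode() for n in group["names"][()]]
    return Montage(names, group["positions_mm"][()])


def save_epochs(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs.update(subject=epochs.subject, sfreq=epochs.sfreq,
                        units=epochs.units, band=epochs.band or "",
                        kind="epochs")
        fh.create_dataset("data", data=epochs.data)
        fh.create_dataset("time", data=epochs.times)
        _write_labels(fh, epochs.labels, _LABEL_COLS)
        if epochs.montage is not None:
            _write_montage(fh, epochs.montage)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        montage = _read_montage(fh["montage"]) if "montage" in fh else None
        return EpochSet(subject=int(fh.attrs["subject"]),
                        data=fh["data"][()], times=fh["time"][()],
                        labels=_read_labels(fh["labels"]),
                        sfreq=float(fh.attrs["sfreq"]), montage=montage,
                        units=str(fh.attrs["units"]),
                        band=str(fh.attrs["band"]) or None)


def save_pseudotrials(path, pseudo: PseudoTrialSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs.update(subject=pseudo.subject, sfreq=pseudo.sfreq,
                        units=pseudo.units, band=pseudo.band or "",
                        state=pseudo.state, kind="pseudotrials")
        fh.create_dataset("data", data=pseudo.traces)
        fh.create_dataset("time", data=pseudo.times)
        _write_labels(fh, pseudo.labels, _PSEUDO_COLS)


def load_pseudotrials(path) -> PseudoTrialSet:
    with h5py.File(path, "r") as fh:
        return PseudoTrialSet(subject=int(fh.attrs["subject"]),
                              traces=fh["data"][()], times=fh["time"][()],
                              labels=_read_labels(fh["labels"]),
                              sfreq=float(fh.attrs["sfreq"]),
                              state=str(fh.attrs["state"]),
                              units=str(fh.attrs["units"]),
                              band=str(fh.attrs["band"]) or None)


def curves_to_frame(curves) -> pd.DataFrame:
    """Long-format table of DecodingCurve objects."""
    rows = []
    for c in curves:
        for t, a in zip(c.window_centers_ms, c.accuracy):
            rows.append({"subject": c.subject, "effect": c.effect,
                         "pool": c.pool, "band": c.band,
                         "time_ms": t, "accuracy": a})
    return pd.DataFrame(rows)


def gmats_to_frame(gmats) -> pd.DataFrame:
    """Long-format table of GeneralizationMatrix objects."""
    rows = []
    for g in gmats:
        for i, tr in enumerate(g.window_centers_ms):
            for j, te in enumerate(g.window_centers_ms):
                rows.append({"subject": g.subject, "effect": g.effect,
                             "pool": g.pool, "train_ms": tr, "test_ms": te,
                             "accuracy": g.accuracy[i, j]})
    return pd.DataFrame(rows)
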