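"""Electrode montage: 10/20-system names, 3-D positions, neighborhood queries.

The default layout is the 64-electrode BioSemi arrangement, taken from MNE's
standard montage database and expressed in millimetres. Neighborhoods are
spheres in 3-D head space; the 50 mm default radius is shared between the
bad-electrode rule and the searchlight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_RADIUS_MM = 50.0


@dataclass
class Montage:
    names: list[str]
    positions_mm: np.ndarray            # (n, 3)
    _dist: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=np.float64)
        if self.positions_mm.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        diff = self.positions_mm[:, None, :] - self.positions_mm[None, :, :]
        self._dist = np.sqrt((diff ** 2).sum(-1))

    def __len__(self) -> int:
        return len(self.names)

    @property
    def distances_mm(self) -> np.ndarray:
        """Symmetric pairwise distance matrix, zero on the diagonal."""
        return self._dist

    def index(self, name: str) -> int:
        return self.names.index(name)

    def neighbors(self, electrode: int | str,
                  radius_mm: float = DEFAULT_RADIUS_MM,
                  include_self: bool = False) -> np.ndarray:
        """Indices of electrodes within ``radius_mm`` of ``electrode``."""
        i = electrode if isinstance(electrode, (int, np.integer)) else self.index(electrode)
        mask = self._dist[i] <= radius_mm
        if not include_self:
            mask[i] = False
        return np.flatnonzero(mask)

    def adjacency(self, radius_mm: float = DEFAULT_RADIUS_MM) -> np.ndarray:
        """Boolean adjacency matrix (no self-loops) at the given radius."""
        adj = self._dist <= radius_mm
        np.fill_diagonal(adj, False)
        return adj

    def subset(self, indices: np.ndarray | list[int]) -> "Montage":
        indices = np.asarray(indices)
        return Montage([self.names[i] for i in indices],
                       self.positions_mm[indices])


def standard_montage(n_electrodes: int = 64) -> Montage:
    """Default 10/20-style layout.

    For 64 electrodes this is the BioSemi64 arrangement; for smaller counts
    (used in scaled-down simulations) a spatially spread subset of the same
    layout is returned.
    """
    import mne

    m = mne.channels.make_standard_montage("biosemi64")
    pos = m.get_positions()["ch_pos"]
    names = list(pos)
    xyz = np.array([pos[n] for n in names]) * 1000.0  # metres -> mm
    full = Montage(names, xyz)
    if n_electrodes == len(full):
        return full
    if not 1 <= n_electrodes <= len(full):
        raise ValueError(f"n_electrodes must be in [1, {len(full)}]")
    # greedy max-min selection keeps the subset spread over the scalp
    chosen = [0]
    d = full.distances_mm
    while len(chosen) < n_electrodes:
        rest = [i for i in range(len(full)) if i not in chosen]
        next_i = max(rest, key=lambda i: min(d[i, j] for j in chosen))
        chosen.append(next_i)
    return full.subset(sorted(chosen))


def write_montage_tsv(montage: Montage, path) -> None:
    """Tab-separated electrode/x/y/z file (mm)."""
    with open(path, "w") as fh:
        fh.write("electrode\tx_mm\ty_mm\tz_mm\n")
        for name, (x, y, z) in zip(montage.names, montage.positions_mm):
            fh.write(f"{name}\t{x:.3f}\t{y:.3f}\t{z:.3f}\n")


def read_montage_tsv(path) -> Montage:
    names, rows = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("electrode"):
            raise ValueError("not a montage TSV (missing header)")
        for line in fh:
            parts = line.split("\t")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return Montage(names, np.array(rows))
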