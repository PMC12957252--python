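"""Distance-based electrode graph for the spatial (GCN) branch.

The adjacency between electrodes i and j is a clamped inverse-square decay
of their 3-D scalp distance:

    w_ij = 1 / (delta * d_ij^2),   A_ij = clamp(w_ij, 0.1, 1)

with decay factor ``delta = 8`` by default.  The floor 0.1 keeps the graph
sparse-in-effect (weak long-range links all collapse to the floor) while
the cap 1 avoids singularities for near-touching electrodes.  Coordinates
are normalized to unit mean radius first, which puts the two clamp
thresholds (w = 1 at d ≈ 0.354, w = 0.1 at d ≈ 1.118) in the middle of the
inter-electrode distance distribution of a human montage.

Graph convolutions use the symmetrically normalized operator
L = D̃^{-1/2} A D̃^{-1/2}, with self-loops A_ii = 1 included in both A and
the degree matrix D̃ (the usual renormalization trick).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElectrodeGraph",
    "build_adjacency",
    "normalized_operator",
    "standard_62_channel_coords",
    "load_coords_csv",
    "save_coords_csv",
    "SEED_62_CHANNELS",
]

# 62-channel ESI NeuroScan montage used by the SEED recordings.  CB1/CB2 sit
# on the inion line and correspond to I1/I2 in 10-05 nomenclature.
SEED_62_CHANNELS = [
    "FP1", "FPZ", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "FZ", "F2",
    "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6",
    "FT8", "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8", "TP7",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8", "P7", "P5", "P3",
    "P1", "PZ", "P2", "P4", "P6", "P8", "PO7", "PO5", "PO3", "POZ", "PO4",
    "PO6", "PO8", "CB1", "O1", "OZ", "O2", "CB2",
]

_ALIASES = {"CB1": "I1", "CB2": "I2"}


def standard_62_channel_coords(normalize: bool = True) -> np.ndarray:
    """3-D positions of the 62 SEED channels from the standard 10-05 montage.

    Positions come from :mod:`mne`'s built-in template head.  With
    ``normalize`` (the default) they are rescaled to unit mean radius about
    the centroid, the scale the adjacency decay ``delta = 8`` is calibrated
    for.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)  # montage rename upstream
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    lookup = {name.upper(): p for name, p in pos.items()}
    coords = np.array([lookup[_ALIASES.get(ch, ch)] for ch in SEED_62_CHANNELS])
    if normalize:
        coords = normalize_coords(coords)
    return coords


def normalize_coords(coords: np.ndarray) -> np.ndarray:
    """Center at the centroid and scale to unit mean radius."""
    coords = np.asarray(coords, dtype=np.float64)
    centered = coords - coords.mean(axis=0)
    radius = np.linalg.norm(centered, axis=1).mean()
    if radius == 0:
        raise ValueError("degenerate coordinates (all points coincide)")
    return centered / radius


def load_coords_csv(path) -> tuple[list[str], np.ndarray]:
    """Read an electrode table ``name,x,y,z`` (header optional)."""
    names, rows = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if parts[0].lower() in {"name", "channel", "ch"}:
                continue
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return names, np.array(rows)


def save_coords_csv(path, names: list[str], coords: np.ndarray) -> None:
    with open(path, "w") as f:
        f.write("name,x,y,z\n")
        for name, (x, y, z) in zip(names, coords):
            f.write(f"{name},{x:.6f},{y:.6f},{z:.6f}\n")


def build_adjacency(coords: np.ndarray, delta: float = 8.0, self_loops: bool = True) -> np.ndarray:
    """Clamped inverse-square-distance adjacency; A_ij in [0.1, 1] for i != j."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    coords = np.asarray(coords, dtype=np.float64)
    C = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(C, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident electrodes (zero distance)")
    A = np.zeros((C, C))
    w = 1.0 / (delta * d[off] ** 2)
    A[off] = np.clip(w, 0.1, 1.0)
    if self_loops:
        np.fill_diagonal(A, 1.0)
    return A


def normalized_operator(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization D̃^{-1/2} A D̃^{-1/2} of a nonnegative adjacency."""
    A = np.asarray(A, dtype=np.float64)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    deg = A.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("zero-degree node in graph")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclass
class ElectrodeGraph:
    """Coordinates, adjacency and normalized graph operator in one place."""

    coords: np.ndarray
    delta: float
    adjacency: np.ndarray
    operator: np.ndarray  # L = D̃^{-1/2} A D̃^{-1/2}

    @staticmethod
    def from_coords(coords: np.ndarray, delta: float = 8.0, self_loops: bool = True) -> "ElectrodeGraph":
        A = build_adjacency(coords, delta=delta, self_loops=self_loops)
        return ElectrodeGraph(coords=np.asarray(coords), delta=delta, adjacency=A, operator=normalized_operator(A))

    @staticmethod
    def standard_62(delta: float = 8.0) -> "ElectrodeGraph":
        return ElectrodeGraph.from_coords(standard_62_channel_coords(), delta=delta)

    @staticmethod
    def uniform(C: int) -> "ElectrodeGraph":
        """Information-free control: every off-diagonal weight at the 0.1 floor.

        Used to test that reconstruction of masked channels actually exploits
        electrode geometry rather than global averages.
        """
        A = np.full((C, C), 0.1)
        np.fill_diagonal(A, 1.0)
        coords = np.zeros((C, 3))
        return ElectrodeGraph(coords=coords, delta=float("nan"), adjacency=A, operator=normalized_operator(A))

    @property
    def n_channels(self) -> int:
        return len(self.adjacency)
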