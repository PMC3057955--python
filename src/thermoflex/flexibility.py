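"""Side-chain rotamer and salt-bridge statistics from trajectory tables.

Arginine side-chain conformations are named by binning χ1–χ3 into the
p/t/m wells (modal values 60°/180°/300°) and χ4 into {85, 180, −85},
e.g. "mtm180".  Bins are half-open [low, high) with boundaries at
0/120/240°.  Salt-bridge persistence is the fraction of frames with a
donor–acceptor distance below a cutoff (4 Å by convention).  Rigid-body
superposition (Kabsch), per-frame RMSD and per-atom RMSF support
backbone-stability checks on coordinate ensembles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DihedralTrace", "RotamerAssignment", "DistanceTrace", "SaltBridgeSummary",
    "classify_rotamer", "classify_rotamers", "rotamer_statistics",
    "salt_bridge_occupancy", "kabsch_superpose", "rmsd_series", "rmsf_per_atom",
    "read_dihedral_csv", "read_distance_csv", "read_xyz_frames", "write_xyz_frames",
]

_CHI_BINS = "ptm"  # [0,120) → p, [120,240) → t, [240,360) → m
_CHI4_BINS = ("85", "180", "-85")


@dataclass(frozen=True)
class DihedralTrace:
    """χ1–χ4 time series for one residue, degrees in [0, 360)."""

    time: np.ndarray  # ps
    chi: np.ndarray  # (n_frames, 4)
    residue_label: str = ""

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        chi = np.mod(np.asarray(self.chi, dtype=float), 360.0)
        if chi.ndim != 2 or chi.shape[1] != 4:
            raise ValueError("chi must be an (n_frames, 4) array")
        if time.shape[0] != chi.shape[0]:
            raise ValueError("time and chi must have equal lengths")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "chi", chi)


@dataclass(frozen=True)
class RotamerAssignment:
    labels: np.ndarray  # per-frame rotamer name
    occupancy: dict  # label → fraction, sums to 1
    transitions: int  # label changes between consecutive frames
    dwell_lengths: dict  # label → list of consecutive-run lengths


@dataclass(frozen=True)
class DistanceTrace:
    time: np.ndarray  # ps
    d: np.ndarray  # Å

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if time.shape != d.shape:
            raise ValueError("time and d must have equal lengths")
        if np.any(d <= 0):
            raise ValueError("distances must be positive")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class SaltBridgeSummary:
    occupancy: float  # fraction of frames with d < cutoff
    mean_d: float
    max_d: float
    cutoff: float


def classify_rotamer(chi) -> str:
    """Rotamer name for one (χ1, χ2, χ3, χ4) quadruple in degrees."""
    c = np.mod(np.asarray(chi, dtype=float), 360.0)
    if c.shape != (4,) or not np.all(np.isfinite(c)):
        raise ValueError("chi must be 4 finite angles")
    idx = np.minimum((c // 120.0).astype(int), 2)
    return "".join(_CHI_BINS[i] for i in idx[:3]) + _CHI4_BINS[idx[3]]


def classify_rotamers(chi) -> np.ndarray:
    """Vectorized rotamer names for an (n, 4) array of angles."""
    c = np.mod(np.asarray(chi, dtype=float), 360.0)
    idx = np.minimum((c // 120.0).astype(int), 2)
    heads = np.char.add(np.char.add(
        np.array(list(_CHI_BINS))[idx[:, 0]],
        np.array(list(_CHI_BINS))[idx[:, 1]]),
        np.array(list(_CHI_BINS))[idx[:, 2]])
    return np.char.add(heads, np.array(_CHI4_BINS)[idx[:, 3]])


def rotamer_statistics(trace: DihedralTrace) -> RotamerAssignment:
    """Per-frame labels, occupancy fractions, transitions and dwell lengths."""
    if trace.chi.shape[0] < 2:
        raise ValueError("need >=2 frames for rotamer statistics")
    labels = classify_rotamers(trace.chi)
    n = labels.size
    uniq, counts = np.unique(labels, return_counts=True)
    occupancy = {str(u): float(c) / n for u, c in zip(uniq, counts)}
    changes = labels[1:] != labels[:-1]
    transitions = int(np.count_nonzero(changes))
    dwell: dict[str, list[int]] = {}
    run_start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[run_start]:
            dwell.setdefault(str(labels[run_start]), []).append(i - run_start)
            run_start = i
    return RotamerAssignment(labels=labels, occupancy=occupancy,
                             transitions=transitions, dwell_lengths=dwell)


def salt_bridge_occupancy(trace: DistanceTrace, cutoff: float = 4.0) -> SaltBridgeSummary:
    """Fraction of frames with donor–acceptor distance below ``cutoff`` Å."""
    d = trace.d
    if d.size == 0:
        raise ValueError("empty distance trace")
    return SaltBridgeSummary(
        occupancy=float(np.count_nonzero(d < cutoff)) / d.size,
        mean_d=float(d.mean()), max_d=float(d.max()), cutoff=cutoff,
    )


def kabsch_superpose(mobile, reference):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in
    the least-squares sense; the rotation is proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("frames must be matching (n_atoms, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("need >=3 atoms for superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-9) < 2 or np.linalg.matrix_rank(Qc, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) geometry")
    V, S, Wt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(V @ Wt))
    D = np.diag([1.0, 1.0, d])
    rot = (V @ D @ Wt).T
    trans = Q.mean(axis=0) - rot @ P.mean(axis=0)
    resid = Pc @ rot.T - Qc
    rmsd = float(np.sqrt((resid**2).sum() / P.shape[0]))
    return rot, trans, rmsd


def rmsd_series(ensemble, reference: int = 0):
    """Per-frame RMSD (Å) against a reference frame after superposition.

    Returns ``(rmsd_array, stable)`` where ``stable`` flags all values
    below 1.5 Å — a common backbone-stability criterion.
    """
    X = np.asarray(ensemble, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("ensemble must be (n_frames, n_atoms, 3)")
    ref = X[reference]
    out = np.array([kabsch_superpose(frame, ref)[2] for frame in X])
    return out, bool(np.all(out < 1.5))


def rmsf_per_atom(ensemble) -> np.ndarray:
    """Per-atom RMSF (Å) about the mean structure.

    Two-pass procedure: frames are first superposed on frame 0 to build
    a mean structure, then re-superposed on that mean; RMSF is the
    square root of the time-averaged squared deviation from the final
    mean.
    """
    X = np.asarray(ensemble, dtype=float)
    if X.ndim != 3 or X.shape[2] != 3:
        raise ValueError("ensemble must be (n_frames, n_atoms, 3)")
    if X.shape[0] < 2:
        raise ValueError("need >=2 frames for RMSF")

    def _superpose_all(frames, ref):
        out = np.empty_like(frames)
        for i, frame in enumerate(frames):
            rot, trans, _ = kabsch_superpose(frame, ref)
            out[i] = frame @ rot.T + trans
        return out

    aligned = _superpose_all(X, X[0])
    mean = aligned.mean(axis=0)
    aligned = _superpose_all(X, mean)
    mean = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# plain-text I/O

def read_dihedral_csv(path, residue_label: str = "") -> DihedralTrace:
    df = pd.read_csv(path)
    return DihedralTrace(time=df["time_ps"].to_numpy(),
                         chi=df[["chi1", "chi2", "chi3", "chi4"]].to_numpy(),
                         residue_label=residue_label)


def read_distance_csv(path) -> DistanceTrace:
    df = pd.read_csv(path)
    return DistanceTrace(time=df["time_ps"].to_numpy(),
                         d=df["distance_A"].to_numpy())


def read_xyz_frames(path):
    """Read a multi-frame XYZ file → (coords (F, N, 3), atom labels)."""
    frames, labels = [], None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            fh.readline()  # comment line
            block, blk_labels = [], []
            for _ in range(n):
                parts = fh.readline().split()
                blk_labels.append(parts[0])
                block.append([float(v) for v in parts[1:4]])
            if labels is None:
                labels = blk_labels
            elif blk_labels != labels:
                raise ValueError("inconsistent atom labels across frames")
            frames.append(block)
    if not frames:
        raise ValueError("no frames in XYZ file")
    return np.asarray(frames, dtype=float), labels


def write_xyz_frames(path, coords, labels=None, comment: str = "") -> None:
    X = np.asarray(coords, dtype=float)
    if labels is None:
        labels = [f"CA" for _ in range(X.shape[1])]
    with open(path, "w") as fh:
        for f, frame in enumerate(X):
            fh.write(f"{frame.shape[0]}\n{comment} frame {f}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
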