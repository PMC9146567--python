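"""Geometric descriptors of stacked tetrads.

The descriptor suite follows standard G4 structural analysis: distances
between tetrad centres of mass, angles subtended at the tetrad centroid by
guanines of the same quartet (ca. 90 deg for adjacent, ca. 180 deg for
opposite pairs in an intact parallel G4), the inter-tetrad twist angle,
and Kabsch-superposed RMSD (per-frame series and pairwise 2D maps).

Twist follows the C1' edge-vector convention: within each tetrad, the four
vectors joining C1' atoms of cyclically adjacent strand columns are
projected onto the plane perpendicular to the channel axis and the twist
is the circular mean of the four signed angles between corresponding
projected vectors of consecutive tetrads; the sign is positive for a
right-handed rotation looking down the axis.  Glycosidic N9 vectors are
offered as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import circmean

from .structure import StructureModel, Trajectory
from .templates import ELEMENT_MASSES
from .topology import Tetrad, TetradTopology, base_com, frame_axis, tetrad_centroid


class DegeneracyError(ValueError):
    """Raised when a geometric fit is ill-defined (collinear points...)."""


@dataclass
class PlaneFit:
    """Least-squares plane through a point set."""

    centroid: np.ndarray
    normal: np.ndarray
    rms_out_of_plane: float


@dataclass
class MetricSeries:
    """Per-frame values of one named descriptor."""

    name: str
    values: np.ndarray
    frames: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.frames is None:
            self.frames = np.arange(len(self.values))
        self.frames = np.asarray(self.frames, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frames, self.name: self.values})

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, lineterminator="\n")
        return path


@dataclass
class RmsdMatrix:
    """Symmetric pairwise RMSD matrix over (possibly strided) frames."""

    values: np.ndarray
    frame_indices: np.ndarray
    selection: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("RMSD matrix must be square")

    @property
    def mean_off_diagonal(self) -> float:
        n = self.values.shape[0]
        if n < 2:
            return 0.0
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.values, index=self.frame_indices,
                     columns=self.frame_indices).to_csv(path, lineterminator="\n")
        return path


# ---------------------------------------------------------------------------
# plane fitting and tetrad descriptors
# ---------------------------------------------------------------------------

def fit_plane(points: np.ndarray, axis_hint: np.ndarray | None = None) -> PlaneFit:
    """Least-squares plane (smallest principal component of centred points).

    With an ``axis_hint`` the normal's sign is chosen to point along it.
    Collinear or insufficient point sets raise :class:`DegeneracyError`.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) < 3:
        raise DegeneracyError("plane fit needs at least 3 points")
    centroid = points.mean(axis=0)
    centred = points - centroid
    _, s, vt = np.linalg.svd(centred)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise DegeneracyError("points are collinear; plane is not defined")
    normal = vt[2] / np.linalg.norm(vt[2])
    if axis_hint is not None and np.dot(normal, axis_hint) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFit(centroid=centroid, normal=normal, rms_out_of_plane=rms)


def guanine_angles(
    model: StructureModel,
    coords: np.ndarray,
    tetrad: Tetrad,
    vertex: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Angles (degrees) subtended at the tetrad centroid by guanine base COMs.

    Returns ``(adjacent, opposite)``: the four angles between cyclically
    neighbouring guanines and the two diagonal angles.  The vertex defaults
    to the centroid of the four base COMs in this frame.
    """
    coms = np.array([base_com(model, coords, g) for g in tetrad.guanines])
    if vertex is None:
        vertex = coms.mean(axis=0)
    vecs = coms - vertex
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-9):
        raise DegeneracyError("a guanine COM coincides with the angle vertex")
    unit = vecs / norms[:, None]

    def angle(i: int, j: int) -> float:
        c = float(np.clip(np.dot(unit[i], unit[j]), -1.0, 1.0))
        return float(np.degrees(np.arccos(c)))

    adjacent = np.array([angle(k, (k + 1) % 4) for k in range(4)])
    opposite = np.array([angle(0, 2), angle(1, 3)])
    return adjacent, opposite


def tetrad_com(model: StructureModel, coords: np.ndarray,
               tetrad: Tetrad) -> np.ndarray:
    """Mass-weighted COM of all heavy atoms of the tetrad's guanine residues."""
    idx = np.concatenate([model.residue_atoms(g) for g in tetrad.guanines])
    heavy = np.char.upper(model.elements[idx].astype(str)) != "H"
    idx = idx[heavy]
    m = np.array([ELEMENT_MASSES.get(str(e).upper(), 0.0)
                  for e in model.elements[idx]])
    return np.average(coords[idx], axis=0, weights=m)


def tetrad_com_distance(model: StructureModel, coords: np.ndarray,
                        tetrad_i: Tetrad, tetrad_j: Tetrad) -> float:
    """Euclidean distance (Å) between guanine heavy-atom COMs of two tetrads."""
    return float(np.linalg.norm(tetrad_com(model, coords, tetrad_i) -
                                tetrad_com(model, coords, tetrad_j)))


def _edge_vectors(model: StructureModel, coords: np.ndarray,
                  tetrad: Tetrad, atom: str) -> np.ndarray:
    pts = np.array([coords[model.atom_index(g, atom)] for g in tetrad.guanines])
    return np.roll(pts, -1, axis=0) - pts


def twist_angle(
    model: StructureModel,
    coords: np.ndarray,
    tetrad_i: Tetrad,
    tetrad_j: Tetrad,
    axis: np.ndarray,
    vectors: str = "c1",
) -> float:
    """Signed inter-tetrad twist (degrees) about ``axis``.

    Requires column-matched tetrads (from ``order_tetrads``); ``vectors``
    selects the C1' (default) or glycosidic N9 edge-vector convention.
    """
    atom = {"c1": "C1'", "n9": "N9"}.get(vectors.lower())
    if atom is None:
        raise ValueError("vectors must be 'c1' or 'n9'")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    try:
        vi = _edge_vectors(model, coords, tetrad_i, atom)
        vj = _edge_vectors(model, coords, tetrad_j, atom)
    except KeyError as err:
        raise ValueError(
            "tetrad columns are unmatched or atoms missing; re-run "
            "order_tetrads on this pair") from err
    vi -= np.outer(vi @ axis, axis)
    vj -= np.outer(vj @ axis, axis)
    angles = np.arctan2((np.cross(vi, vj) @ axis),
                        np.einsum("ij,ij->i", vi, vj))
    return float(np.degrees(circmean(angles, high=np.pi, low=-np.pi)))


# ---------------------------------------------------------------------------
# Kabsch superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class KabschResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    degenerate: bool = False


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None = None,
) -> KabschResult:
    """Least-RMSD proper-rotation superposition of X onto Y.

    Returns rotation R and translation t minimising
    sqrt(sum_i w_i ||R x_i + t - y_i||^2 / sum_i w_i); reflections are
    excluded.  Collinear point sets yield a flagged (non-unique) result.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    Y = np.asarray(Y, dtype=float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise ValueError("point sets must have matching shapes")
    if len(X) < 3:
        raise ValueError("superposition needs at least 3 points")
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    xbar = np.average(X, axis=0, weights=w)
    ybar = np.average(Y, axis=0, weights=w)
    degenerate = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rot, _ = Rotation.align_vectors(Y - ybar, X - xbar, weights=w)
        degenerate = any("Optimal rotation is not uniquely" in str(c.message)
                         for c in caught)
    R = rot.as_matrix()
    t = ybar - R @ xbar
    # evaluate the residual directly: the closed-form rssd loses precision
    # to cancellation near zero, which matters for invariance checks
    residual = (X @ R.T + t) - Y
    rmsd = float(np.sqrt(np.sum(w * np.sum(residual ** 2, axis=1)) / wsum))
    return KabschResult(rotation=R, translation=t, rmsd=rmsd,
                        degenerate=degenerate)


def _batched_rmsd(A: np.ndarray, B: np.ndarray,
                  weights: np.ndarray | None = None) -> np.ndarray:
    """Minimal proper-rotation RMSD for m matched point-set pairs at once.

    A, B: (m, n, 3).  Uses the Kabsch closed form with batched SVD and the
    determinant sign correction that excludes reflections.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m, n, _ = A.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    wa = w[None, :, None]
    Ac = A - (A * wa).sum(axis=1, keepdims=True) / wsum
    Bc = B - (B * wa).sum(axis=1, keepdims=True) / wsum
    H = np.einsum("mni,mnj->mij", Ac * wa, Bc)
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", U, Vt)))
    S[:, -1] *= sign
    e0 = np.einsum("mni,mni->m", Ac * wa, Ac) + np.einsum("mni,mni->m", Bc * wa, Bc)
    msd = np.maximum(e0 - 2.0 * S.sum(axis=1), 0.0) / wsum
    return np.sqrt(msd)


def rmsd_series(
    traj: Trajectory,
    selection: np.ndarray,
    reference_frame: int = 0,
    weights: np.ndarray | None = None,
    name: str = "rmsd",
) -> MetricSeries:
    """Per-frame Kabsch RMSD of a selection against one reference frame."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    sub = traj.frames[:, selection, :]
    ref = np.broadcast_to(sub[reference_frame], sub.shape)
    values = _batched_rmsd(ref, sub, weights=weights)
    return MetricSeries(name=name, values=values, units="Å")


def rmsd_matrix(
    traj: Trajectory,
    selection: np.ndarray,
    stride: int | None = None,
    weights: np.ndarray | None = None,
    max_frames: int = 2000,
) -> RmsdMatrix:
    """Pairwise 2D-RMSD map between all retained frame pairs.

    ``stride`` defaults to the smallest value keeping the matrix at or
    below ``max_frames`` per side.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    n = traj.n_frames
    if stride is None:
        stride = max(1, int(np.ceil(n / max_frames)))
    if stride < 1:
        raise ValueError("stride must be >= 1")
    keep = np.arange(0, n, stride)
    sub = traj.frames[keep][:, selection, :]
    k = len(keep)
    out = np.zeros((k, k))
    ii, jj = np.triu_indices(k, k=1)
    # chunked so the batched SVD never materializes an enormous stack
    chunk = max(1, int(2e7 // max(selection.size, 1)))
    for start in range(0, len(ii), chunk):
        sl = slice(start, start + chunk)
        vals = _batched_rmsd(sub[ii[sl]], sub[jj[sl]], weights=weights)
        out[ii[sl], jj[sl]] = vals
        out[jj[sl], ii[sl]] = vals
    return RmsdMatrix(values=out, frame_indices=keep, selection=selection)


def aligned_mean_structure(
    traj: Trajectory,
    n_frames: int | None = None,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Average structure after Kabsch-aligning frames onto frame 0.

    Rigid motion is removed frame by frame (fit on ``selection``, applied
    to all atoms) before averaging the first ``n_frames`` frames, so
    coordinate noise shrinks as 1/sqrt(n) and the mean is a low-noise
    stand-in for the underlying reference geometry.
    """
    k = traj.n_frames if n_frames is None else min(n_frames, traj.n_frames)
    sel = np.arange(traj.model.n_atoms) if selection is None else \
        np.asarray(selection, dtype=int)
    ref = traj.frames[0]
    acc = ref.copy()
    for f in range(1, k):
        fit = kabsch_superpose(traj.frames[f][sel], ref[sel])
        acc += traj.frames[f] @ fit.rotation.T + fit.translation
    return acc / k


# ---------------------------------------------------------------------------
# per-frame descriptor series over a trajectory
# ---------------------------------------------------------------------------

def twist_series(
    traj: Trajectory,
    topology: TetradTopology,
    pair: tuple[int, int] = (0, 1),
    vectors: str = "c1",
) -> MetricSeries:
    """Inter-tetrad twist per frame for one tetrad pair (indices into the stack)."""
    i, j = pair
    ti, tj = topology.tetrads[i], topology.tetrads[j]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        axis, _ = frame_axis(traj.model, topology, coords)
        values[f] = twist_angle(traj.model, coords, ti, tj, axis, vectors=vectors)
    return MetricSeries(name=f"twist_{i}{j}", values=values, units="deg")


def com_distance_series(
    traj: Trajectory, topology: TetradTopology, pair: tuple[int, int] = (0, 1),
) -> MetricSeries:
    """Tetrad COM distance per frame for one tetrad pair."""
    i, j = pair
    ti, tj = topology.tetrads[i], topology.tetrads[j]
    values = np.array([
        tetrad_com_distance(traj.model, traj.frames[f], ti, tj)
        for f in range(traj.n_frames)
    ])
    return MetricSeries(name=f"com_distance_{i}{j}", values=values, units="Å")


def angle_series(
    traj: Trajectory, topology: TetradTopology, tetrad_index: int = 0,
) -> tuple[MetricSeries, MetricSeries]:
    """Mean adjacent and mean opposite guanine angle per frame for one tetrad."""
    tet = topology.tetrads[tetrad_index]
    adj = np.empty(traj.n_frames)
    opp = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        a, o = guanine_angles(traj.model, traj.frames[f], tet)
        adj[f], opp[f] = a.mean(), o.mean()
    return (
        MetricSeries(name=f"adjacent_angle_t{tetrad_index}", values=adj, units="deg"),
        MetricSeries(name=f"opposite_angle_t{tetrad_index}", values=opp, units="deg"),
    )
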