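"""Tetrad detection, stacking order, loop and channel-ion assignment.

A guanine tetrad is a cyclic arrangement of four guanines in which each
guanine donates its Watson-Crick edge (N1-H, N2-H) to the Hoogsteen edge
(O6, N7) of its neighbour.  Detection here is purely geometric: a directed
Hoogsteen pair i -> j is recorded when both heavy-atom donor-acceptor
distances N1(i)-O6(j) and N2(i)-N7(j) fall below a cutoff (3.5 Å by
default — a conventional heavy-atom hydrogen-bond criterion chosen so that
structures without hydrogens, such as lesioned models, can be analysed),
and tetrads are the simple directed 4-cycles of the resulting graph.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .structure import StructureModel
from .templates import BASE_ATOMS, ELEMENT_MASSES

DEFAULT_HBOND_CUTOFF = 3.5  # Å, heavy-atom donor-acceptor

_HOOGSTEEN_ATOMS = ("N1", "N2", "O6", "N7")
_GUANINE_NAMES = ("DG", "G", "GUA")


@dataclass(frozen=True)
class HoogsteenPair:
    """A directed Hoogsteen contact donor -> acceptor between two guanines."""

    donor_res: int
    acceptor_res: int
    d_n1_o6: float
    d_n2_n7: float

    @property
    def mean_distance(self) -> float:
        return 0.5 * (self.d_n1_o6 + self.d_n2_n7)


@dataclass(frozen=True)
class Tetrad:
    """Cyclically ordered guanine quadruple (residue indices).

    The cyclic order follows the Hoogsteen donor -> acceptor direction and
    is canonicalized to start at the smallest residue index.
    """

    guanines: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(set(self.guanines)) != 4:
            raise ValueError("a tetrad needs 4 distinct guanines")

    @staticmethod
    def from_cycle(cycle) -> "Tetrad":
        cycle = [int(g) for g in cycle]
        k = int(np.argmin(cycle))
        return Tetrad(tuple(cycle[k:] + cycle[:k]))


@dataclass
class TetradTopology:
    """Tetrads ordered along the channel axis, plus loops and channel ions."""

    tetrads: list[Tetrad]
    axis: np.ndarray
    loops: list[tuple[int, ...]] = field(default_factory=list)
    overhangs: list[tuple[int, ...]] = field(default_factory=list)
    channel_ions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    axis_degenerate: bool = False

    @property
    def tetrad_resids(self) -> np.ndarray:
        return np.array([g for t in self.tetrads for g in t.guanines], dtype=int)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "tetrads": [list(t.guanines) for t in self.tetrads],
            "axis": [float(x) for x in self.axis],
            "loops": [list(run) for run in self.loops],
            "overhangs": [list(run) for run in self.overhangs],
            "channel_ions": [int(i) for i in self.channel_ions],
            "axis_degenerate": bool(self.axis_degenerate),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @staticmethod
    def from_json(text: str) -> "TetradTopology":
        payload = json.loads(text)
        return TetradTopology(
            tetrads=[Tetrad(tuple(g)) for g in payload["tetrads"]],
            axis=np.asarray(payload["axis"], dtype=float),
            loops=[tuple(run) for run in payload["loops"]],
            overhangs=[tuple(run) for run in payload["overhangs"]],
            channel_ions=np.asarray(payload["channel_ions"], dtype=int),
            axis_degenerate=payload["axis_degenerate"],
        )


# ---------------------------------------------------------------------------
# guanine bookkeeping
# ---------------------------------------------------------------------------

def guanine_resids(model: StructureModel) -> list[int]:
    """Residue numbers of guanines, in strand order."""
    out: list[int] = []
    seen: set[int] = set()
    for resid, resname in zip(model.resids, model.resnames):
        if str(resname).strip().upper() in _GUANINE_NAMES and resid not in seen:
            seen.add(int(resid))
            out.append(int(resid))
    return out


def _hoogsteen_atom_indices(model: StructureModel):
    """Per-guanine indices of N1, N2, O6, N7; guanines missing one are skipped."""
    resids, rows = [], []
    for resid in guanine_resids(model):
        try:
            rows.append([model.atom_index(resid, a) for a in _HOOGSTEEN_ATOMS])
        except KeyError:
            warnings.warn(
                f"guanine {resid} lacks a Hoogsteen atom; skipped in detection")
            continue
        resids.append(resid)
    return np.array(resids, dtype=int), np.array(rows, dtype=int).reshape(-1, 4)


def hoogsteen_distance_arrays(model: StructureModel, coords: np.ndarray):
    """(resids, d_N1O6 matrix, d_N2N7 matrix) over all ordered guanine pairs."""
    resids, rows = _hoogsteen_atom_indices(model)
    if len(resids) == 0:
        return resids, np.empty((0, 0)), np.empty((0, 0))
    n1, n2, o6, n7 = (coords[rows[:, k]] for k in range(4))
    d_n1_o6 = np.linalg.norm(n1[:, None, :] - o6[None, :, :], axis=-1)
    d_n2_n7 = np.linalg.norm(n2[:, None, :] - n7[None, :, :], axis=-1)
    return resids, d_n1_o6, d_n2_n7


def detect_hoogsteen_pairs(
    model: StructureModel,
    coords: np.ndarray | None = None,
    dmax: float = DEFAULT_HBOND_CUTOFF,
) -> list[HoogsteenPair]:
    """Directed Hoogsteen pairs i -> j with both donor-acceptor distances <= dmax."""
    if coords is None:
        coords = model.coordinates
    resids, d1, d2 = hoogsteen_distance_arrays(model, coords)
    pairs: list[HoogsteenPair] = []
    hit = (d1 <= dmax) & (d2 <= dmax)
    np.fill_diagonal(hit, False)
    for i, j in np.argwhere(hit):
        pairs.append(HoogsteenPair(int(resids[i]), int(resids[j]),
                                   float(d1[i, j]), float(d2[i, j])))
    pairs.sort(key=lambda p: (p.donor_res, p.acceptor_res))
    return pairs


# ---------------------------------------------------------------------------
# tetrads
# ---------------------------------------------------------------------------

def find_tetrads(pairs: list[HoogsteenPair]) -> list[Tetrad]:
    """Simple directed 4-cycles of the donor -> acceptor graph.

    Each guanine joins at most one tetrad; if a guanine belongs to several
    candidate cycles the cycle with the smaller mean donor-acceptor distance
    wins, ties broken by residue indices.  Output is sorted by smallest
    residue index.
    """
    graph = nx.DiGraph()
    dist = {}
    for p in pairs:
        graph.add_edge(p.donor_res, p.acceptor_res)
        dist[(p.donor_res, p.acceptor_res)] = p.mean_distance
    candidates = []
    for cycle in nx.simple_cycles(graph, length_bound=4):
        if len(cycle) != 4:
            continue
        tet = Tetrad.from_cycle(cycle)
        edges = list(zip(tet.guanines, tet.guanines[1:] + tet.guanines[:1]))
        mean_d = float(np.mean([dist[e] for e in edges]))
        candidates.append((mean_d, tet.guanines, tet))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used: set[int] = set()
    tetrads: list[Tetrad] = []
    for _, _, tet in candidates:
        if used.isdisjoint(tet.guanines):
            used.update(tet.guanines)
            tetrads.append(tet)
    tetrads.sort(key=lambda t: min(t.guanines))
    return tetrads


def base_com(model: StructureModel, coords: np.ndarray, resid: int) -> np.ndarray:
    """Mass-weighted centre of mass of a residue's base heavy atoms."""
    resname = str(model.resnames[model.residue_atoms(resid)[0]])
    from .templates import canonical_resname
    canon = canonical_resname(resname)
    names = BASE_ATOMS[canon] if canon else None
    idx = model.residue_atoms(resid, names)
    if len(idx) == 0:
        raise ValueError(f"residue {resid} has no base heavy atoms")
    m = np.array([ELEMENT_MASSES.get(str(e).upper(), 0.0)
                  for e in model.elements[idx]])
    return np.average(coords[idx], axis=0, weights=m)


def tetrad_centroid(model: StructureModel, coords: np.ndarray,
                    tetrad: Tetrad) -> np.ndarray:
    """Centroid of the four guanine base centres of mass."""
    return np.mean([base_com(model, coords, g) for g in tetrad.guanines], axis=0)


def tetrad_normal(model: StructureModel, coords: np.ndarray,
                  tetrad: Tetrad) -> np.ndarray:
    """Unit normal of the best-fit plane through the four base COMs."""
    pts = np.array([base_com(model, coords, g) for g in tetrad.guanines])
    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[2] / np.linalg.norm(vt[2])


def _axis_sign(model: StructureModel, coords: np.ndarray,
               tetrads: list[Tetrad], axis: np.ndarray) -> float:
    """+1 if the axis runs 5'->3' along the strands, else -1."""
    members = sorted(g for t in tetrads for g in t.guanines)
    proj = {g: float(np.dot(base_com(model, coords, g), axis)) for g in members}
    score = 0.0
    for g in members:
        if g + 1 in proj:  # strand-adjacent tetrad guanines (same G-tract)
            score += proj[g + 1] - proj[g]
    return -1.0 if score < 0 else 1.0


def _align_columns(reference: Tetrad, other: Tetrad) -> Tetrad:
    """Rotate (or reverse) ``other``'s cyclic order to match strand columns.

    Column k of every tetrad should lie on the same strand when strand
    continuity allows; the rotation maximising the number of columns whose
    residue is strand-adjacent to the reference column is chosen, ties
    broken by the smaller total residue offset.
    """
    ref = reference.guanines
    best = None
    for order in (other.guanines, other.guanines[::-1]):
        for r in range(4):
            cand = tuple(order[(k + r) % 4] for k in range(4))
            adjacency = sum(abs(cand[k] - ref[k]) == 1 for k in range(4))
            offset = sum(abs(cand[k] - ref[k]) for k in range(4))
            key = (-adjacency, offset, cand)
            if best is None or key < best[0]:
                best = (key, cand)
    return Tetrad(best[1])


def order_tetrads(
    tetrads: list[Tetrad],
    model: StructureModel,
    coords: np.ndarray | None = None,
) -> TetradTopology:
    """Sort tetrads along the channel axis and align their strand columns.

    The axis is the principal direction through the tetrad centroids, with
    its sign fixed to run 5'->3' along the strands.  With a single tetrad
    the axis is that tetrad's plane normal; with coincident centroids the
    mean tetrad normal is used and the topology is flagged degenerate.
    """
    if not tetrads:
        raise ValueError("at least one tetrad is required")
    if coords is None:
        coords = model.coordinates
    centroids = np.array([tetrad_centroid(model, coords, t) for t in tetrads])
    degenerate = False
    if len(tetrads) == 1:
        axis = tetrad_normal(model, coords, tetrads[0])
    else:
        centred = centroids - centroids.mean(axis=0)
        u, s, vt = np.linalg.svd(centred)
        if s[0] < 1e-8:  # coincident centroids
            degenerate = True
            normals = np.array([tetrad_normal(model, coords, t) for t in tetrads])
            normals[1:] *= np.sign(normals[1:] @ normals[0])[:, None]
            axis = normals.mean(axis=0)
        else:
            axis = vt[0]
    axis = axis / np.linalg.norm(axis)
    axis = axis * _axis_sign(model, coords, tetrads, axis)
    order = np.argsort(centroids @ axis, kind="stable")
    stacked = [tetrads[k] for k in order]
    aligned = [stacked[0]]
    for t in stacked[1:]:
        aligned.append(_align_columns(aligned[-1], t))
    return TetradTopology(tetrads=aligned, axis=axis, axis_degenerate=degenerate)


# ---------------------------------------------------------------------------
# loops, ions, full detection
# ---------------------------------------------------------------------------

def assign_loops(model: StructureModel, topology: TetradTopology) -> TetradTopology:
    """Fill in loop runs (and 5'/3' overhangs) of non-tetrad residues."""
    resids = model.residue_ids
    members = set(int(g) for t in topology.tetrads for g in t.guanines)
    runs: list[tuple[int, ...]] = []
    current: list[int] = []
    for r in resids:
        if int(r) in members:
            if current:
                runs.append(tuple(current))
                current = []
        else:
            current.append(int(r))
    if current:
        runs.append(tuple(current))
    if members:
        lo, hi = min(members), max(members)
        topology.loops = [run for run in runs if run[0] > lo and run[-1] < hi]
        topology.overhangs = [run for run in runs if run[0] < lo or run[-1] > hi]
    else:
        topology.loops, topology.overhangs = [], runs
    return topology


def frame_axis(model: StructureModel, topology: TetradTopology,
               coords: np.ndarray):
    """(axis, centroids) of the fixed tetrad membership in one frame.

    Membership is tracked from the detection frame; only the geometry is
    re-evaluated, which makes every downstream descriptor invariant under
    rigid motion of the frame.
    """
    centroids = np.array([tetrad_centroid(model, coords, t)
                          for t in topology.tetrads])
    if len(centroids) == 1:
        axis = tetrad_normal(model, coords, topology.tetrads[0])
    else:
        centred = centroids - centroids.mean(axis=0)
        _, s, vt = np.linalg.svd(centred)
        if s[0] < 1e-8:
            normals = np.array([tetrad_normal(model, coords, t)
                                for t in topology.tetrads])
            normals[1:] *= np.sign(normals[1:] @ normals[0])[:, None]
            axis = normals.mean(axis=0)
        else:
            axis = vt[0]
    axis = axis / np.linalg.norm(axis)
    axis = axis * _axis_sign(model, coords, topology.tetrads, axis)
    return axis, centroids


def assign_channel_ions(model: StructureModel, topology: TetradTopology,
                        coords: np.ndarray | None = None,
                        radius: float = 3.0, margin: float = 2.0) -> TetradTopology:
    """Register ions inside the channel cylinder at the detection frame."""
    if coords is None:
        coords = model.coordinates
    if len(model.ions) == 0 or not topology.tetrads:
        topology.channel_ions = np.empty(0, dtype=int)
        return topology
    axis, centroids = frame_axis(model, topology, coords)
    origin = centroids.mean(axis=0)
    proj = centroids @ axis
    lo, hi = proj.min() - margin, proj.max() + margin
    rel = coords[model.ions] - origin
    axial = rel @ axis + origin @ axis
    radial = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
    inside = (radial <= radius) & (axial >= lo) & (axial <= hi)
    topology.channel_ions = model.ions[inside]
    return topology


def detect_topology(
    model: StructureModel,
    coords: np.ndarray | None = None,
    dmax: float = DEFAULT_HBOND_CUTOFF,
    channel_radius: float = 3.0,
    channel_margin: float = 2.0,
) -> TetradTopology:
    """Full pipeline: Hoogsteen pairs -> tetrads -> stacking order -> loops/ions."""
    if coords is None:
        coords = model.coordinates
    pairs = detect_hoogsteen_pairs(model, coords, dmax=dmax)
    tetrads = find_tetrads(pairs)
    if not tetrads:
        raise ValueError("no tetrads detected; not a folded G4 at this cutoff")
    topology = order_tetrads(tetrads, model, coords)
    assign_loops(model, topology)
    assign_channel_ions(model, topology, coords,
                        radius=channel_radius, margin=channel_margin)
    return topology
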