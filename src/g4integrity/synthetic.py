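"""Synthetic G4 models and conformational ensembles.

The builder assembles an idealized three-tetrad parallel G-quadruplex:
planar guanine bases placed at exact 4-fold rotations in each tetrad
plane, tetrad k rotated by ``k * twist`` about the channel axis and raised
by ``k * rise``, TTA-style loops laid out as smooth outer arcs, and one
channel cation on the axis midway between consecutive tetrad planes.  The
in-plane base orientation is calibrated once (see
``scripts/derive_tetrad_calibration.py``) so that the Hoogsteen
donor-acceptor heavy-atom distances are exactly 2.9 Å; the calibrated
constants are frozen below.

The ensemble generator adds i.i.d. Gaussian coordinate noise with a
rigid-core / flexible-loop structure (loop noise defaults to 4x the core
noise), an optional global random rigid motion per frame (on by default so
that invariance bugs surface in tests), and deterministic injected
destabilization events (cation leakage, guanine expulsion).  The noise is
statistical, not physical: it emulates the variance structure of a stable
MD ensemble, not its dynamics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import topology as topo
from .breaks import HTELO_SEQUENCE
from .structure import StructureModel, Trajectory
from .templates import (BASE_FRAME, base_frame_array, element_from_name,
                        residue_bond_template)

# frozen tetrad calibration (derive_tetrad_calibration.py):
# in-plane base rotation, C1' azimuth, and C1' radius giving Hoogsteen
# N1-O6 and N2-N7 heavy-atom distances of exactly 2.9 Å
TETRAD_PHI = 3.407295557661139
TETRAD_ALPHA = 5.623502679790102
DEFAULT_C1_RADIUS = 8.207209622367104

_FRACTIONS = {
    # fractional position along the C1'(i) -> C1'(i+1) segment and
    # perpendicular offsets (Å) used to lay out the sugar-phosphate chain
    "C2'": (0.10, 0.6, -0.3),
    "C3'": (0.22, 0.9, 0.1),
    "O3'": (0.33, 0.8, 0.0),
    "P": (0.60, 0.8, 0.0),
    "O5'": (0.72, 0.6, 0.0),
    "C5'": (0.82, 0.5, -0.2),
    "C4'": (0.90, 0.3, 0.0),
    "O4'": (0.90, 0.3, -1.2),
}


@dataclass
class BuilderParams:
    """Geometry of the ideal parallel G4."""

    n_tetrads: int = 3
    rise: float = 3.3          # Å between consecutive tetrad planes
    twist: float = 30.0        # degrees between consecutive tetrads
    c1_radius: float = DEFAULT_C1_RADIUS  # Å, C1' distance from the axis
    sequence: str = HTELO_SEQUENCE
    loop_bulge: float = 4.0    # Å of extra radius at mid-loop

    def __post_init__(self) -> None:
        if self.n_tetrads < 1:
            raise ValueError("n_tetrads must be >= 1")
        if self.rise <= 0 or self.c1_radius <= 0:
            raise ValueError("rise and c1_radius must be positive")


@dataclass(frozen=True)
class InjectedEvent:
    """A deterministic destabilization event applied from ``frame`` onward."""

    kind: str                 # "cation_leak" | "guanine_expulsion"
    frame: int
    magnitude: float          # Å of radial displacement
    ion: int | None = None    # index into model.ions (cation_leak)
    resid: int | None = None  # residue number (guanine_expulsion)

    def __post_init__(self) -> None:
        if self.kind not in ("cation_leak", "guanine_expulsion"):
            raise ValueError(f"unknown injected event kind {self.kind!r}")


@dataclass
class EnsembleParams:
    """Stochastic structure of the synthetic ensemble."""

    n_frames: int
    seed: int
    sigma_core: float = 0.4        # Å per coordinate, tetrad residues + ions
    sigma_loop: float | None = None  # Å, defaults to 4x sigma_core
    rigid_motion: bool = True
    events: tuple[InjectedEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.sigma_core < 0 or (self.sigma_loop or 0) < 0:
            raise ValueError("noise levels must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic generation")

    @property
    def effective_sigma_loop(self) -> float:
        return 4.0 * self.sigma_core if self.sigma_loop is None else self.sigma_loop


def _rz(deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _find_tracts(sequence: str, n_tetrads: int) -> list[list[int]]:
    """1-based residue numbers of the four G-tracts, or raise."""
    runs = [(m.start() + 1, m.end()) for m in re.finditer("G+", sequence)]
    tracts = [list(range(a, b + 1)) for a, b in runs if b - a + 1 == n_tetrads]
    if len(tracts) != 4 or any(b - a + 1 != n_tetrads for a, b in runs):
        raise ValueError(
            f"sequence {sequence!r} is incompatible with 4 G-tracts of "
            f"length {n_tetrads}")
    return tracts


def _guanine_template(params: BuilderParams) -> dict[str, np.ndarray]:
    """Full heavy-atom template of a tetrad guanine at column 0, tetrad 0.

    Base + C1' come from the calibrated in-plane placement; the
    sugar-phosphate atoms are laid along the helical C1' -> C1' segment of
    the G-tract so that every tetrad guanine is an exact rigid image of
    this template (which makes twist/rise recovery exact at zero noise).
    """
    names, base = base_frame_array("DG")
    c1_2d = np.array(BASE_FRAME["DG"]["C1'"] + (0.0,))
    rot = _rz(np.degrees(TETRAD_PHI))
    anchor = params.c1_radius * np.array(
        [np.cos(TETRAD_ALPHA), np.sin(TETRAD_ALPHA), 0.0])
    placed = (base - c1_2d) @ rot.T + anchor
    template = dict(zip(names, placed))

    c1 = template["C1'"]
    twist = params.twist if params.n_tetrads > 1 else 30.0
    c1_next = _rz(twist) @ c1 + np.array([0.0, 0.0, params.rise])
    seg = _backbone_between(c1, c1_next)
    for name in ("C2'", "C3'", "O3'"):
        template[name] = seg["a"][name]
    down = _rz(-twist)
    shift = np.array([0.0, 0.0, params.rise])
    for name in ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'"):
        template[name] = down @ (seg["b"][name] - shift)
    return template


def _backbone_between(c1_a: np.ndarray, c1_b: np.ndarray) -> dict:
    """Sugar-phosphate atoms along one internucleotide C1' segment.

    Returns {'a': {C2', C3', O3'}, 'b': {P, OP1, OP2, O5', C5', C4', O4'}} —
    the upstream residue's 3' side and the downstream residue's 5' side.
    """
    seg = c1_b - c1_a
    length = np.linalg.norm(seg)
    u = seg / max(length, 1e-9)
    mid = 0.5 * (c1_a + c1_b)
    radial = mid - np.array([0.0, 0.0, mid[2]])
    w1 = radial - (radial @ u) * u
    if np.linalg.norm(w1) < 1e-6:
        w1 = np.array([1.0, 0.0, 0.0]) - u[0] * u
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(u, w1)

    def at(name: str) -> np.ndarray:
        f, o1, o2 = _FRACTIONS[name]
        return c1_a + f * seg + o1 * w1 + o2 * w2

    out_a = {name: at(name) for name in ("C2'", "C3'", "O3'")}
    out_b = {name: at(name) for name in ("P", "O5'", "C5'", "C4'", "O4'")}
    p = out_b["P"]
    d1 = (w1 + w2) / np.sqrt(2.0)
    d2 = (w1 - w2) / np.sqrt(2.0)
    out_b["OP1"] = p + 1.48 * d1
    out_b["OP2"] = p + 1.48 * d2
    return {"a": out_a, "b": out_b}


def _loop_residue(resname: str, anchor: np.ndarray, azimuth_deg: float) -> dict:
    """Base + C1' of a loop residue, planar, oriented to its azimuth."""
    names, base = base_frame_array(resname)
    c1_2d = np.array(BASE_FRAME[resname]["C1'"] + (0.0,))
    rot = _rz(azimuth_deg + 180.0)  # base points outward from the core
    placed = (base - c1_2d) @ rot.T + anchor
    return dict(zip(names, placed))


def build_ideal_g4(params: BuilderParams | None = None) -> StructureModel:
    """Build an ideal parallel G4 :class:`StructureModel`.

    Tetrad guanines are exact rigid images of one calibrated template;
    loop residues are placed on smooth outer arcs; one channel cation sits
    on the axis midway between consecutive tetrad planes.  Connectivity is
    the parallel-strand wiring of the sequence.
    """
    params = params or BuilderParams()
    sequence = params.sequence.upper()
    tracts = _find_tracts(sequence, params.n_tetrads)
    n_res = len(sequence)

    template = _guanine_template(params)
    tract_of: dict[int, tuple[int, int]] = {}   # resid -> (column, tetrad)
    for s, tract in enumerate(tracts):
        for t, resid in enumerate(tract):
            tract_of[resid] = (s, t)

    # C1' anchors for loop interpolation
    c1_col0 = template["C1'"]

    def tetrad_atom(name: str, s: int, t: int) -> np.ndarray:
        rot = _rz(90.0 * s + params.twist * t)
        return rot @ template[name] + np.array([0.0, 0.0, params.rise * t])

    # ---- anchors (C1' positions) for every residue ----------------------
    anchors: dict[int, np.ndarray] = {}
    azimuths: dict[int, float] = {}
    for resid, (s, t) in tract_of.items():
        anchors[resid] = tetrad_atom("C1'", s, t)
        azimuths[resid] = np.degrees(np.arctan2(anchors[resid][1],
                                                anchors[resid][0]))
    base_radius = float(np.linalg.norm(c1_col0[:2]))
    top_t = params.n_tetrads - 1

    def arc(start_resid: int, end_resid: int, resids: list[int]) -> None:
        """Lay loop anchors on an outward-bulged arc between two guanines."""
        a0, a1 = anchors[start_resid], anchors[end_resid]
        th0 = np.degrees(np.arctan2(a0[1], a0[0]))
        th1 = np.degrees(np.arctan2(a1[1], a1[0]))
        dth = (th1 - th0) % 360.0
        for j, resid in enumerate(resids, start=1):
            f = j / (len(resids) + 1)
            th = th0 + f * dth
            r = base_radius + params.loop_bulge * np.sin(np.pi * f)
            z = (1.0 - f) * a0[2] + f * a1[2]
            anchors[resid] = np.array([r * np.cos(np.radians(th)),
                                       r * np.sin(np.radians(th)), z])
            azimuths[resid] = th

    loop_resids: set[int] = set()
    for s in range(3):
        start = tracts[s][top_t]
        end = tracts[s + 1][0]
        run = list(range(start + 1, end))
        loop_resids.update(run)
        if run:
            arc(start, end, run)
    # 5' overhang: extrapolate below the first tract; 3' overhang above last
    head = list(range(1, tracts[0][0]))
    for j, resid in enumerate(reversed(head), start=1):
        ref = anchors[tracts[0][0]]
        th = azimuths[tracts[0][0]] - 35.0 * j
        r = base_radius + 1.5
        anchors[resid] = np.array([r * np.cos(np.radians(th)),
                                   r * np.sin(np.radians(th)),
                                   ref[2] - 1.2 * j])
        azimuths[resid] = th
        loop_resids.add(resid)
    tail = list(range(tracts[3][-1] + 1, n_res + 1))
    for j, resid in enumerate(tail, start=1):
        ref = anchors[tracts[3][-1]]
        th = azimuths[tracts[3][-1]] + 35.0 * j
        r = base_radius + 1.5
        anchors[resid] = np.array([r * np.cos(np.radians(th)),
                                   r * np.sin(np.radians(th)),
                                   ref[2] + 1.2 * j])
        azimuths[resid] = th
        loop_resids.add(resid)

    # ---- assemble atoms -------------------------------------------------
    resname_of = {"G": "DG", "A": "DA", "T": "DT", "C": "DC"}
    atom_names: list[str] = []
    elements: list[str] = []
    resids: list[int] = []
    resnames: list[str] = []
    coords: list[np.ndarray] = []

    def virtual_anchor(before: int) -> np.ndarray:
        """Extrapolated anchor used at chain ends."""
        if before == 1:
            return anchors[1] - (anchors[2] - anchors[1])
        return anchors[n_res] + (anchors[n_res] - anchors[n_res - 1])

    backbone_order = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                      "C1'", "C2'", "C3'", "O3'")
    for resid in range(1, n_res + 1):
        letter = sequence[resid - 1]
        resname = resname_of[letter]
        if resid in tract_of:
            s, t = tract_of[resid]
            positions = {name: tetrad_atom(name, s, t) for name in template}
        else:
            positions = _loop_residue(resname, anchors[resid], azimuths[resid])
            prev_anchor = anchors[resid - 1] if resid > 1 else virtual_anchor(1)
            next_anchor = anchors[resid + 1] if resid < n_res \
                else virtual_anchor(n_res + 1)
            seg_prev = _backbone_between(prev_anchor, anchors[resid])
            seg_next = _backbone_between(anchors[resid], next_anchor)
            positions.update(seg_prev["b"])
            positions.update({k: v for k, v in seg_next["a"].items()})
        if resid == 1:  # 5' terminus carries no phosphate
            for name in ("P", "OP1", "OP2"):
                positions.pop(name, None)
        ordered = [n for n in backbone_order if n in positions] + \
            [n for n in positions if n not in backbone_order]
        for name in ordered:
            atom_names.append(name)
            elements.append(element_from_name(name))
            resids.append(resid)
            resnames.append(resname)
            coords.append(positions[name])

    # ---- channel cations ------------------------------------------------
    ion_indices: list[int] = []
    for t in range(params.n_tetrads - 1):
        ion_indices.append(len(atom_names))
        atom_names.append("K")
        elements.append("K")
        resids.append(n_res + 1 + t)
        resnames.append("K")
        coords.append(np.array([0.0, 0.0, params.rise * (t + 0.5)]))

    model = StructureModel(
        atom_names=np.array(atom_names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chain_ids=np.array(["A"] * len(atom_names), dtype=object),
        coordinates=np.array(coords),
        ions=np.array(ion_indices, dtype=int),
    )

    # ---- connectivity ---------------------------------------------------
    bonds: set[tuple[int, int]] = set()
    for resid in range(1, n_res + 1):
        resname = resname_of[sequence[resid - 1]]
        names = {str(model.atom_names[i]): int(i)
                 for i in model.residue_atoms(resid)}
        for a, b in residue_bond_template(resname):
            if a in names and b in names:
                i, j = names[a], names[b]
                bonds.add((min(i, j), max(i, j)))
    for resid in range(1, n_res):
        i = model.atom_index(resid, "O3'")
        j = model.atom_index(resid + 1, "P")
        bonds.add((min(i, j), max(i, j)))
    model.bonds = bonds
    return model


def core_residues(model: StructureModel,
                  dmax: float = topo.DEFAULT_HBOND_CUTOFF) -> np.ndarray:
    """Tetrad guanine residue numbers, found by Hoogsteen detection."""
    pairs = topo.detect_hoogsteen_pairs(model, dmax=dmax)
    tetrads = topo.find_tetrads(pairs)
    return np.array(sorted(g for t in tetrads for g in t.guanines), dtype=int)


def _uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized 4-Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def generate_ensemble(
    model: StructureModel,
    params: EnsembleParams,
    core_resids: np.ndarray | None = None,
) -> Trajectory:
    """Generate a stochastic conformational ensemble around a model.

    Frame t is the model plus independent Gaussian noise (``sigma_core``
    on tetrad residues and ions, ``sigma_loop`` elsewhere), an optional
    global random rigid motion, and any injected events active at t.
    Events displace atoms deterministically from their onset frame: a
    cation is pushed radially off the axis, an expelled guanine is
    translated radially outward while its Hoogsteen partners stay put.
    """
    rng = np.random.default_rng(params.seed)
    if core_resids is None:
        core_resids = core_residues(model)
    core_resids = np.asarray(core_resids, dtype=int)

    sigma = np.full(model.n_atoms, params.effective_sigma_loop)
    sigma[np.isin(model.resids, core_resids)] = params.sigma_core
    sigma[model.ions] = params.sigma_core

    # channel axis for event displacement directions (frame-0 geometry)
    if len(core_resids):
        pairs = topo.detect_hoogsteen_pairs(model)
        tetrads = topo.find_tetrads(pairs)
        axis = topo.order_tetrads(tetrads, model).axis if tetrads \
            else np.array([0.0, 0.0, 1.0])
    else:
        axis = np.array([0.0, 0.0, 1.0])

    def radial_direction(point: np.ndarray) -> np.ndarray:
        rel = point - (point @ axis) * axis
        norm = np.linalg.norm(rel)
        if norm < 1e-6:
            rel = np.array([1.0, 0.0, 0.0]) - axis[0] * axis
            norm = np.linalg.norm(rel)
        return rel / norm

    displacements: list[tuple[int, np.ndarray, np.ndarray]] = []
    for ev in params.events:
        if ev.kind == "cation_leak":
            if not len(model.ions):
                raise ValueError("cation_leak event but the model has no ions")
            ion_pos = ev.ion if ev.ion is not None else 0
            idx = np.array([model.ions[ion_pos]])
            direction = radial_direction(model.coordinates[idx[0]])
        else:  # guanine_expulsion
            if ev.resid is None:
                raise ValueError("guanine_expulsion event needs a resid")
            idx = model.residue_atoms(ev.resid)
            com = model.coordinates[idx].mean(axis=0)
            direction = radial_direction(com)
        displacements.append((ev.frame, idx, ev.magnitude * direction))

    frames = np.empty((params.n_frames, model.n_atoms, 3))
    for f in range(params.n_frames):
        base = model.coordinates.copy()
        for onset, idx, shift in displacements:
            if f >= onset:
                base[idx] += shift
        noise = rng.normal(size=(model.n_atoms, 3)) * sigma[:, None]
        frame = base + noise
        if params.rigid_motion:
            rot = _uniform_rotation(rng)
            trans = rng.normal(scale=5.0, size=3)
            frame = frame @ rot.T + trans
        frames[f] = frame
    return Trajectory(model=model, frames=frames)
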