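"""Structures, conformational ensembles and atom selection.

The in-memory containers are deliberately light: a :class:`StructureModel`
is a set of flat numpy arrays describing the topology (names, residues,
connectivity, ions) and one coordinate set, and a :class:`Trajectory` adds
a stack of per-frame coordinates.  File I/O and the selection grammar are
delegated to MDAnalysis; the containers convert to and from an
``mda.Universe`` at this module's boundary only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import templates


class FormatError(ValueError):
    """Raised for malformed or unwritable structure files."""


class SelectionError(ValueError):
    """Raised for malformed selection strings."""


@dataclass(eq=False)
class StructureModel:
    """Atoms, one coordinate set (Å), connectivity and cation bookkeeping."""

    atom_names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chain_ids: np.ndarray
    coordinates: np.ndarray
    bonds: set[tuple[int, int]] = field(default_factory=set)
    ions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    #: residue -> terminal-chemistry labels (e.g. "3'-OH"), set by apply_breaks
    termini: dict[int, tuple[str, ...]] = field(default_factory=dict)
    #: per-break annotations (label, chemistry, positions, phosphate owner)
    break_annotations: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        self.ions = np.asarray(self.ions, dtype=int)
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates must be finite")
        n = self.n_atoms
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references missing atoms")
        self._index_cache: dict[tuple[int, str], int] | None = None
        self._universe = None

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([templates.ELEMENT_MASSES.get(str(e).upper(), 0.0)
                         for e in self.elements])

    @property
    def residue_ids(self) -> np.ndarray:
        """Distinct residue numbers of the nucleic chain, in file order."""
        mask = np.ones(self.n_atoms, bool)
        mask[self.ions] = False
        _, first = np.unique(self.resids[mask], return_index=True)
        return np.sort(self.resids[mask][np.sort(first)])

    def atom_index(self, resid: int, name: str) -> int:
        """Flat index of atom ``name`` in residue ``resid`` (KeyError if absent)."""
        if self._index_cache is None:
            self._index_cache = {
                (int(r), str(n)): i
                for i, (r, n) in enumerate(zip(self.resids, self.atom_names))
            }
        return self._index_cache[(int(resid), str(name))]

    def residue_atoms(self, resid: int, names: tuple[str, ...] | None = None) -> np.ndarray:
        """Indices of (optionally named) atoms belonging to one residue."""
        mask = self.resids == int(resid)
        if names is not None:
            mask &= np.isin(self.atom_names, list(names))
        return np.flatnonzero(mask)

    def copy(self) -> "StructureModel":
        return StructureModel(
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            chain_ids=self.chain_ids.copy(),
            coordinates=self.coordinates.copy(),
            bonds=set(self.bonds),
            ions=self.ions.copy(),
            termini=dict(self.termini),
            break_annotations=[dict(b) for b in self.break_annotations],
        )

    # -- MDAnalysis bridge -------------------------------------------------
    def to_universe(self, frames: np.ndarray | None = None):
        """Build an ``mda.Universe`` carrying this topology (and coordinates)."""
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        n = self.n_atoms
        # MDAnalysis groups residues by (resid, resname, segment) in order
        res_keys = list(zip(self.resids.tolist(), self.resnames.tolist(),
                            self.chain_ids.tolist()))
        unique: list[tuple] = []
        atom_resindex = np.empty(n, dtype=int)
        for i, key in enumerate(res_keys):
            if not unique or unique[-1] != key:
                unique.append(key)
            atom_resindex[i] = len(unique) - 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(
                n, n_residues=len(unique), atom_resindex=atom_resindex,
                n_segments=1, residue_segindex=np.zeros(len(unique), dtype=int),
                trajectory=True,
            )
            u.add_TopologyAttr("ids", list(range(1, n + 1)))
            u.add_TopologyAttr("names", self.atom_names.astype(str).tolist())
            u.add_TopologyAttr("elements", self.elements.astype(str).tolist())
            u.add_TopologyAttr("resids", [k[0] for k in unique])
            u.add_TopologyAttr("resnames", [k[1] for k in unique])
            u.add_TopologyAttr("chainIDs", self.chain_ids.astype(str).tolist())
            record = np.where(np.isin(np.arange(n), self.ions), "HETATM", "ATOM")
            u.add_TopologyAttr("record_types", record.tolist())
            u.add_TopologyAttr("occupancies", [1.0] * n)
            u.add_TopologyAttr("tempfactors", [0.0] * n)
            if self.bonds:
                u.add_bonds(sorted(self.bonds))
            coords = self.coordinates[None] if frames is None else np.asarray(frames)
            u.load_new(coords.astype(np.float64), format=MemoryReader)
        return u


@dataclass(eq=False)
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (Å)."""

    model: StructureModel
    frames: np.ndarray
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame of shape (n_atoms, 3)")
        if self.frames.shape[1] != self.model.n_atoms:
            raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _scan_models(path: Path) -> list[int]:
    """Per-MODEL atom counts from raw PDB text (one implicit model allowed)."""
    counts: list[int] = []
    current = 0
    in_model = False
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if not saw_model:
        counts = [current]
    elif in_model:
        counts.append(current)
    return counts


def _infer_connectivity(model: StructureModel) -> set[tuple[int, int]]:
    """Template-based heavy-atom connectivity for standard deoxynucleotides.

    Intra-residue bonds come from per-residue templates; phosphodiester
    O3'(i)-P(i+1) bonds are added only when the two atoms are within bonding
    distance, so chain breaks present in the input geometry are preserved.
    """
    bonds: set[tuple[int, int]] = set()
    order: list[tuple[str, int]] = []  # (chain, resid) in file order, ions excluded
    ion_set = set(model.ions.tolist())
    for i in range(model.n_atoms):
        if i in ion_set:
            continue
        key = (str(model.chain_ids[i]), int(model.resids[i]))
        if not order or order[-1] != key:
            order.append(key)
    for chain, resid in order:
        sel = np.flatnonzero((model.resids == resid) & (model.chain_ids == chain))
        resname = str(model.resnames[sel[0]])
        try:
            template = templates.residue_bond_template(resname)
        except KeyError:
            warnings.warn(f"unknown residue {resname!r} (resid {resid}): "
                          "template connectivity skipped")
            continue
        names = {str(model.atom_names[i]): int(i) for i in sel}
        for a, b in template:
            if a in names and b in names:
                i, j = names[a], names[b]
                bonds.add((min(i, j), max(i, j)))
    for (chain_a, res_a), (chain_b, res_b) in zip(order, order[1:]):
        if chain_a != chain_b:
            continue
        try:
            i = model.atom_index(res_a, "O3'")
            j = model.atom_index(res_b, "P")
        except KeyError:
            continue
        d = np.linalg.norm(model.coordinates[i] - model.coordinates[j])
        if d <= templates.O3P_BOND_CUTOFF:
            bonds.add((min(i, j), max(i, j)))
    return bonds


def read_pdb(path: str | Path) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    Each MODEL becomes one frame.  K+/Na+ HETATM records are registered as
    ions.  CONECT records are honored when present; otherwise heavy-atom
    connectivity is inferred from nucleotide templates plus inter-residue
    O3'-P bonds gated by distance.
    """
    import MDAnalysis as mda

    path = Path(path)
    counts = _scan_models(path)
    if len(set(counts)) > 1:
        raise FormatError(
            f"atom count differs across models in {path.name}: {sorted(set(counts))}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = u.atoms.names.astype(object)
        resids = u.atoms.resids.astype(int)
        resnames = u.atoms.resnames.astype(object)
        try:
            chains = u.atoms.chainIDs.astype(object)
        except Exception:
            chains = np.array(["A"] * len(names), dtype=object)
        try:
            elements = u.atoms.elements.astype(object)
        except Exception:
            elements = np.array(
                [templates.element_from_name(n) for n in names], dtype=object)
        elements = np.array(
            [e if str(e).strip() else templates.element_from_name(n)
             for e, n in zip(elements, names)], dtype=object)
        frames = np.stack([u.atoms.positions.astype(float).copy()
                           for _ in u.trajectory])
        conect = {tuple(sorted(map(int, b.indices))) for b in u.bonds} \
            if hasattr(u, "bonds") else set()

    ion_mask = np.isin(np.char.upper(elements.astype(str)),
                       list(templates.ION_ELEMENTS)) | \
        np.isin(np.char.upper(resnames.astype(str)), list(templates.ION_RESNAMES))
    model = StructureModel(
        atom_names=names, elements=elements, resids=resids, resnames=resnames,
        chain_ids=chains, coordinates=frames[0],
        ions=np.flatnonzero(ion_mask),
    )
    model.bonds = conect if conect else _infer_connectivity(model)
    return Trajectory(model=model, frames=frames)


def write_pdb(traj: Trajectory | StructureModel, path: str | Path) -> Path:
    """Write a trajectory (or single model) as a multi-model PDB with CONECT."""
    import MDAnalysis as mda

    if isinstance(traj, StructureModel):
        traj = Trajectory(model=traj, frames=traj.coordinates[None])
    path = Path(path)
    lo, hi = traj.frames.min(), traj.frames.max()
    if lo < -999.999 or hi > 9999.999:
        raise FormatError(
            f"coordinates [{lo:.2f}, {hi:.2f}] exceed the fixed-width PDB range")
    u = traj.model.to_universe(frames=traj.frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, bonds="all",
                        reindex=False) as writer:
            for _ in u.trajectory:
                writer.write(u.atoms)
    return path


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

_ALL_BASE_NAMES = sorted({a for names in templates.BASE_ATOMS.values() for a in names})

_MACROS = {
    "base": "(name " + " ".join(_ALL_BASE_NAMES) + ")",
    "sugar": "(name " + " ".join(templates.SUGAR_ATOMS) + ")",
    "backbone": "(name " + " ".join(templates.BACKBONE_ATOMS) + ")",
    "anything": "all",
}


def select(model: StructureModel, spec: str) -> np.ndarray:
    """Resolve a selection string to a sorted array of atom indices.

    The grammar is MDAnalysis selection syntax (``resname``, ``resid``
    ranges, ``name``, ``element``, ``and``/``or``/``not`` ...) extended with
    the macros ``base``, ``sugar``, ``backbone``, ``ions`` and ``anything``.
    """
    from MDAnalysis.exceptions import SelectionError as MdaSelectionError

    if not isinstance(spec, str) or not spec.strip():
        raise SelectionError("selection spec must be a non-empty string")
    if len(model.ions):
        ion_expr = "(index " + " ".join(map(str, model.ions.tolist())) + ")"
    else:
        ion_expr = "(name __no_ions__)"
    expanded = spec
    for word, replacement in ({"ions": ion_expr, "ion": ion_expr} |
                              _MACROS).items():
        expanded = re.sub(rf"\b{word}\b", replacement, expanded,
                          flags=re.IGNORECASE)
    if model._universe is None:
        model._universe = model.to_universe()
    try:
        group = model._universe.select_atoms(expanded)
    except (MdaSelectionError, ValueError) as err:
        raise SelectionError(f"malformed selection {spec!r}: {err}") from err
    return np.sort(group.indices.astype(int))


def heavy_atom_indices(model: StructureModel, resids) -> np.ndarray:
    """Non-hydrogen atom indices of the given residues (ions excluded)."""
    resids = np.atleast_1d(np.asarray(resids, dtype=int))
    mask = np.isin(model.resids, resids)
    mask &= np.char.upper(model.elements.astype(str)) != "H"
    mask[model.ions] = False
    return np.flatnonzero(mask)


def nucleic_heavy_indices(model: StructureModel) -> np.ndarray:
    """All nucleic heavy atoms (whole-DNA selection used for global RMSD)."""
    mask = np.char.upper(model.elements.astype(str)) != "H"
    mask[model.ions] = False
    return np.flatnonzero(mask)


def tetrad_core_indices(model: StructureModel, tetrad_resids) -> np.ndarray:
    """Base + sugar heavy atoms of tetrad guanines (the 'tetrads only' selection)."""
    resids = np.atleast_1d(np.asarray(tetrad_resids, dtype=int))
    names = set(_ALL_BASE_NAMES) | set(templates.SUGAR_ATOMS)
    mask = np.isin(model.resids, resids)
    mask &= np.isin(model.atom_names, list(names))
    return np.flatnonzero(mask)
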