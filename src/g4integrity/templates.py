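"""Idealized nucleotide geometry and connectivity templates.

Planar base coordinates are the standard reference-frame geometries of
Olson et al. (1999) for the DNA bases, given as (x, y) pairs in Å with the
base lying in the z = 0 plane and C1' included so that a glycosidic anchor
is available.  They serve two purposes: connectivity inference for PDB
files without CONECT records, and rigid base placement in the synthetic
builder.
"""

from __future__ import annotations

import numpy as np

# masses of the heavy elements that occur in nucleic acids plus channel cations
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "K": 39.098,
    "NA": 22.990,
}

#: standard reference-frame base coordinates (Å), z = 0
BASE_FRAME: dict[str, dict[str, tuple[float, float]]] = {
    "DG": {
        "C1'": (-2.477, 5.399),
        "N9": (-1.289, 4.551),
        "C8": (0.023, 4.962),
        "N7": (0.870, 3.969),
        "C5": (0.071, 2.833),
        "C6": (0.424, 1.460),
        "O6": (1.554, 0.955),
        "N1": (-0.700, 0.641),
        "C2": (-1.999, 1.087),
        "N2": (-2.949, 0.139),
        "N3": (-2.342, 2.364),
        "C4": (-1.265, 3.177),
    },
    "DA": {
        "C1'": (-2.479, 5.346),
        "N9": (-1.291, 4.498),
        "C8": (0.024, 4.897),
        "N7": (0.877, 3.902),
        "C5": (0.071, 2.771),
        "C6": (0.369, 1.398),
        "N6": (1.611, 0.909),
        "N1": (-0.668, 0.532),
        "C2": (-1.912, 1.023),
        "N3": (-2.320, 2.290),
        "C4": (-1.267, 3.124),
    },
    "DT": {
        "C1'": (-2.481, 5.354),
        "N1": (-1.284, 4.500),
        "C2": (-1.462, 3.135),
        "O2": (-2.562, 2.608),
        "N3": (-0.298, 2.407),
        "C4": (0.994, 2.897),
        "O4": (1.944, 2.119),
        "C5": (1.106, 4.338),
        "C7": (2.466, 4.961),
        "C6": (-0.024, 5.057),
    },
    "DC": {
        "C1'": (-2.477, 5.402),
        "N1": (-1.285, 4.542),
        "C2": (-1.472, 3.158),
        "O2": (-2.628, 2.709),
        "N3": (-0.391, 2.344),
        "C4": (0.837, 2.868),
        "N4": (1.875, 2.027),
        "C5": (1.056, 4.275),
        "C6": (-0.023, 5.068),
    },
}

#: base heavy atoms per residue type (glycosidic sugar atom C1' excluded)
BASE_ATOMS: dict[str, tuple[str, ...]] = {
    name: tuple(a for a in frame if a != "C1'") for name, frame in BASE_FRAME.items()
}

SUGAR_ATOMS: tuple[str, ...] = ("C1'", "C2'", "C3'", "C4'", "O4'")
PHOSPHATE_ATOMS: tuple[str, ...] = ("P", "OP1", "OP2")
BACKBONE_ATOMS: tuple[str, ...] = PHOSPHATE_ATOMS + ("O5'", "C5'") + SUGAR_ATOMS + ("O3'",)

#: intra-residue backbone/sugar bonds shared by all deoxynucleotides
_BACKBONE_BONDS: tuple[tuple[str, str], ...] = (
    ("P", "OP1"),
    ("P", "OP2"),
    ("P", "O5'"),
    ("O5'", "C5'"),
    ("C5'", "C4'"),
    ("C4'", "O4'"),
    ("C4'", "C3'"),
    ("C3'", "O3'"),
    ("C3'", "C2'"),
    ("C2'", "C1'"),
    ("C1'", "O4'"),
)

_BASE_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "DG": (
        ("C1'", "N9"),
        ("N9", "C8"),
        ("C8", "N7"),
        ("N7", "C5"),
        ("C5", "C6"),
        ("C6", "O6"),
        ("C6", "N1"),
        ("N1", "C2"),
        ("C2", "N2"),
        ("C2", "N3"),
        ("N3", "C4"),
        ("C4", "C5"),
        ("C4", "N9"),
    ),
    "DA": (
        ("C1'", "N9"),
        ("N9", "C8"),
        ("C8", "N7"),
        ("N7", "C5"),
        ("C5", "C6"),
        ("C6", "N6"),
        ("C6", "N1"),
        ("N1", "C2"),
        ("C2", "N3"),
        ("N3", "C4"),
        ("C4", "C5"),
        ("C4", "N9"),
    ),
    "DT": (
        ("C1'", "N1"),
        ("N1", "C2"),
        ("C2", "O2"),
        ("C2", "N3"),
        ("N3", "C4"),
        ("C4", "O4"),
        ("C4", "C5"),
        ("C5", "C7"),
        ("C5", "C6"),
        ("C6", "N1"),
    ),
    "DC": (
        ("C1'", "N1"),
        ("N1", "C2"),
        ("C2", "O2"),
        ("C2", "N3"),
        ("N3", "C4"),
        ("C4", "N4"),
        ("C4", "C5"),
        ("C5", "C6"),
        ("C6", "N1"),
    ),
}

#: residue-name aliases found in deposited files
RESNAME_ALIASES: dict[str, str] = {
    "DG": "DG", "G": "DG", "GUA": "DG",
    "DA": "DA", "A": "DA", "ADE": "DA",
    "DT": "DT", "T": "DT", "THY": "DT",
    "DC": "DC", "C": "DC", "CYT": "DC",
}

ION_RESNAMES: frozenset[str] = frozenset({"K", "POT", "NA", "SOD"})
ION_ELEMENTS: frozenset[str] = frozenset({"K", "NA"})

#: maximum O3'(i)-P(i+1) distance for inferring a phosphodiester bond (Å)
O3P_BOND_CUTOFF = 2.0


def canonical_resname(resname: str) -> str | None:
    """Map a residue name to its canonical DNA template name, or None."""
    return RESNAME_ALIASES.get(resname.strip().upper())


def residue_bond_template(resname: str) -> tuple[tuple[str, str], ...]:
    """Intra-residue heavy-atom bond list (backbone + base) for a residue type."""
    canon = canonical_resname(resname)
    if canon is None:
        raise KeyError(f"no template for residue {resname!r}")
    return _BACKBONE_BONDS + _BASE_BONDS[canon]


def element_from_name(name: str) -> str:
    """Guess the element from a PDB atom name (heavy atoms and cations only)."""
    stripped = name.strip().upper()
    if stripped in ("K", "NA", "K+", "NA+"):
        return stripped.rstrip("+")
    for ch in stripped:
        if ch.isalpha():
            return ch
    raise ValueError(f"cannot infer element from atom name {name!r}")


def base_frame_array(resname: str) -> tuple[list[str], np.ndarray]:
    """Names and (n, 3) coordinates of a base template, z = 0 plane."""
    canon = canonical_resname(resname)
    if canon is None:
        raise KeyError(f"no base frame for residue {resname!r}")
    frame = BASE_FRAME[canon]
    names = list(frame)
    xy = np.array([frame[n] for n in names], dtype=float)
    coords = np.zeros((len(names), 3))
    coords[:, :2] = xy
    return names, coords
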