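"""Strand-break lesions on G4-forming sequences.

A strand break severs one phosphodiester backbone bond.  Ionizing
radiation produces two chemistries: canonical (CA) breaks leave a
5'-phosphate / 3'-hydroxyl pair of termini and are ligatable, while
non-canonical (NC) breaks leave 5'-hydroxyl / 3'-phosphate ends that are
poorly repaired.  Break positions are written in star notation, e.g.
``A G*GG TTA ...`` for a break between residues 2 and 3 (1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: the human telomeric reference sequence
HTELO_SEQUENCE = "AGGGTTAGGGTTAGGGTTAGGG"

#: default damage scheme over the h-telo sequence: upstream positions of
#: single tetrad-backbone breaks, pairs for double breaks, and loop breaks
DEFAULT_SINGLE_POSITIONS: tuple[int, ...] = (2, 3, 9, 14, 15, 21)
DEFAULT_DOUBLE_PAIRS: tuple[tuple[int, int], ...] = (
    (2, 3), (2, 14), (3, 9), (3, 14), (3, 15), (14, 15),
)
#: loop break positions default to the first junction inside each TTA loop;
#: configurable because deposited schemes rarely state them numerically
DEFAULT_LOOP_POSITIONS: tuple[int, ...] = (5, 11, 17)

STAR = "★"
_STAR_ALIASES = {STAR, "*"}
_VALID_CODES = set("ACGT")


class ParseError(ValueError):
    """Malformed star-notation text."""


class PositionError(ValueError):
    """A break position outside the valid range of the sequence/model."""


class Chemistry(str, Enum):
    """Terminal chemistry of a strand break."""

    CA = "CA"  # canonical: 3'-OH upstream, 5'-PO4 downstream
    NC = "NC"  # non-canonical: 3'-PO4 upstream, 5'-OH downstream

    @property
    def upstream_terminus(self) -> str:
        return "3'-OH" if self is Chemistry.CA else "3'-PO4"

    @property
    def downstream_terminus(self) -> str:
        return "5'-PO4" if self is Chemistry.CA else "5'-OH"

    @property
    def phosphate_owner(self) -> str:
        """Which side of the cut keeps the bridging phosphate."""
        return "downstream" if self is Chemistry.CA else "upstream"


@dataclass(frozen=True, order=True)
class StrandBreak:
    """A backbone cut between residues ``upstream_pos`` and ``upstream_pos+1``."""

    upstream_pos: int
    chemistry: Chemistry = Chemistry.CA

    @property
    def downstream_pos(self) -> int:
        return self.upstream_pos + 1


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.replace(" ", "").upper()
    if len(sequence) < 1:
        raise ParseError("sequence must contain at least one nucleotide")
    bad = set(sequence) - _VALID_CODES
    if bad:
        raise ParseError(f"non-nucleotide codes in sequence: {sorted(bad)}")
    return sequence


def site_class(sequence: str, brk: StrandBreak) -> str:
    """'tetrad' when the cut backbone directly connects two guanines, else 'loop'."""
    seq = _validate_sequence(sequence)
    i = brk.upstream_pos
    if not 1 <= i < len(seq):
        raise PositionError(f"break {i}-{i + 1} outside sequence of length {len(seq)}")
    return "tetrad" if seq[i - 1] == "G" and seq[i] == "G" else "loop"


@dataclass(frozen=True)
class BreakConfig:
    """A set of strand-break lesions on one nucleotide sequence."""

    sequence: str
    breaks: tuple[StrandBreak, ...] = ()
    label: str = "Native"

    def __post_init__(self) -> None:
        seq = _validate_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        breaks = tuple(sorted(set(self.breaks)))
        positions = [b.upstream_pos for b in breaks]
        if len(set(positions)) != len(positions):
            raise PositionError(f"duplicate break positions: {positions}")
        for b in breaks:
            if not 1 <= b.upstream_pos < len(seq):
                raise PositionError(
                    f"break {b.upstream_pos}-{b.downstream_pos} outside "
                    f"sequence of length {len(seq)}")
        object.__setattr__(self, "breaks", breaks)

    @property
    def site_classes(self) -> tuple[str, ...]:
        return tuple(site_class(self.sequence, b) for b in self.breaks)


def make_label(breaks: Sequence[StrandBreak]) -> str:
    """Human-readable label, e.g. 'CA 3-4/14-15' or 'NC 14-15-16' or 'Native'."""
    if not breaks:
        return "Native"
    breaks = sorted(breaks)
    chems = {b.chemistry for b in breaks}
    if len(chems) != 1:
        raise ValueError("mixed-chemistry configurations are not labelled")
    positions = [b.upstream_pos for b in breaks]
    groups: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p == groups[-1][-1] + 1:
            groups[-1].append(p)
        else:
            groups.append([p])
    parts = ["-".join(str(x) for x in g + [g[-1] + 1]) for g in groups]
    return f"{breaks[0].chemistry.value} " + "/".join(parts)


def parse_star_notation(text: str, chemistry: Chemistry | str = Chemistry.CA,
                        ) -> BreakConfig:
    """Parse a star-annotated sequence string into a :class:`BreakConfig`.

    A star (``★`` or the ASCII alias ``*``) marks a break between the two
    letters that flank it; whitespace is ignored for numbering.
    """
    chemistry = Chemistry(chemistry)
    letters: list[str] = []
    star_positions: list[int] = []
    pending_star = False
    for ch in text:
        if ch.isspace():
            continue
        if ch in _STAR_ALIASES:
            if not letters or pending_star:
                raise PositionError(
                    "star must sit between two nucleotide letters")
            pending_star = True
            star_positions.append(len(letters))
        else:
            if ch.upper() not in _VALID_CODES:
                raise ParseError(f"non-nucleotide character {ch!r}")
            letters.append(ch.upper())
            pending_star = False
    if pending_star:
        raise PositionError("star at end of sequence has no downstream residue")
    breaks = tuple(StrandBreak(p, chemistry) for p in star_positions)
    return BreakConfig(sequence="".join(letters), breaks=breaks,
                       label=make_label(breaks))


def render_star_notation(config: BreakConfig) -> str:
    """Render a config back to star notation, grouped in the triplet convention.

    ``parse_star_notation(render_star_notation(c), chem) == c`` for every
    valid config.  Letters are grouped with a leading ``len(seq) % 3`` group
    (if any) followed by triplets, e.g. ``A GGG TTA ...`` for the 22-mer.
    """
    seq = config.sequence
    star_after = {b.upstream_pos for b in config.breaks}
    head = len(seq) % 3
    group_ends = list(range(head, len(seq) + 1, 3)) if head else \
        list(range(3, len(seq) + 1, 3))
    out: list[str] = []
    for i, letter in enumerate(seq, start=1):
        out.append(letter)
        if i in star_after:
            out.append(STAR)
        if i in group_ends and i != len(seq):
            out.append(" ")
    return "".join(out)


def enumerate_damage_scheme(
    sequence: str = HTELO_SEQUENCE,
    single_positions: Iterable[int] = DEFAULT_SINGLE_POSITIONS,
    double_pairs: Iterable[tuple[int, int]] = DEFAULT_DOUBLE_PAIRS,
    loop_positions: Iterable[int] = DEFAULT_LOOP_POSITIONS,
) -> list[BreakConfig]:
    """Enumerate the full damage scheme over a sequence.

    Single and double tetrad-backbone breaks are generated in both CA and
    NC chemistry; loop breaks in CA only.  With the default h-telo scheme
    (6 singles, 6 doubles, 3 loop positions) this yields 27 configurations,
    2 * (6 + 6) + 3.
    """
    singles = list(single_positions)
    doubles = [tuple(p) for p in double_pairs]
    loops = list(loop_positions)
    if len(set(singles)) != len(singles):
        raise PositionError(f"duplicate single-break positions: {singles}")
    if len(set(doubles)) != len(doubles):
        raise PositionError(f"duplicate double-break pairs: {doubles}")
    if len(set(loops)) != len(loops):
        raise PositionError(f"duplicate loop-break positions: {loops}")
    for a, b in doubles:
        if a == b:
            raise PositionError(f"double break pair ({a}, {b}) repeats a position")

    configs: list[BreakConfig] = []
    for chem in (Chemistry.CA, Chemistry.NC):
        for pos in singles:
            brk = (StrandBreak(pos, chem),)
            configs.append(BreakConfig(sequence, brk, make_label(brk)))
        for a, b in doubles:
            brk = (StrandBreak(a, chem), StrandBreak(b, chem))
            configs.append(BreakConfig(sequence, brk, make_label(brk)))
    for pos in loops:
        brk = (StrandBreak(pos, Chemistry.CA),)
        configs.append(BreakConfig(sequence, brk, make_label(brk) + " (loop)"))
    labels = [c.label for c in configs]
    if len(set(labels)) != len(labels):
        raise PositionError("damage scheme produced duplicate labels")
    return configs


def apply_breaks(model, config: BreakConfig):
    """Return a copy of ``model`` with the config's backbone bonds severed.

    Coordinates are untouched; for each break the O3'(upstream)-P(downstream)
    bond is removed from the connectivity table and the flanking residues are
    annotated with their terminal chemistry.  The bridging phosphate is
    assigned to the downstream residue for CA breaks and to the upstream
    residue for NC breaks (an annotation: atoms are not rebuilt).
    """
    out = model.copy()
    resids = set(out.resids[np.setdiff1d(np.arange(out.n_atoms), out.ions)].tolist()) \
        if len(out.ions) else set(out.resids.tolist())
    termini = dict(out.termini)
    for brk in config.breaks:
        up, down = brk.upstream_pos, brk.downstream_pos
        if up not in resids or down not in resids:
            raise PositionError(f"break {up}-{down} outside model residues")
        try:
            i = out.atom_index(up, "O3'")
            j = out.atom_index(down, "P")
        except KeyError as err:
            raise PositionError(
                f"model lacks backbone atoms for break {up}-{down}") from err
        bond = (min(i, j), max(i, j))
        if bond not in out.bonds:
            raise PositionError(
                f"no backbone bond present between residues {up} and {down}")
        out.bonds.discard(bond)
        termini[up] = tuple(sorted(set(termini.get(up, ())) |
                                   {brk.chemistry.upstream_terminus}))
        termini[down] = tuple(sorted(set(termini.get(down, ())) |
                                     {brk.chemistry.downstream_terminus}))
        out.break_annotations.append({
            "label": config.label,
            "chemistry": brk.chemistry.value,
            "upstream": up,
            "downstream": down,
            "phosphate_owner": up if brk.chemistry.phosphate_owner == "upstream"
            else down,
        })
    out.termini = termini
    return out


# ---------------------------------------------------------------------------
# plain-text break tables
# ---------------------------------------------------------------------------

def write_break_table(configs: Sequence[BreakConfig], path: str | Path) -> Path:
    """Write configs as a CSV table (label, chemistry, star_notation)."""
    rows = []
    for c in configs:
        chems = {b.chemistry.value for b in c.breaks}
        rows.append({
            "label": c.label,
            "chemistry": "/".join(sorted(chems)) if chems else "",
            "star_notation": render_star_notation(c),
        })
    path = Path(path)
    pd.DataFrame(rows, columns=["label", "chemistry", "star_notation"]).to_csv(
        path, index=False, lineterminator="\n")
    return path


def read_break_table(path: str | Path) -> list[BreakConfig]:
    """Read a CSV break table written by :func:`write_break_table`."""
    df = pd.read_csv(path, keep_default_na=False)
    configs = []
    for _, row in df.iterrows():
        chem = str(row["chemistry"]) or "CA"
        cfg = parse_star_notation(str(row["star_notation"]), Chemistry(chem))
        configs.append(BreakConfig(cfg.sequence, cfg.breaks, str(row["label"])))
    return configs
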