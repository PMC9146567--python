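"""Analysis thresholds, loadable from a TOML file.

Every operational cutoff of the pipeline lives here so that a single
config file documents an analysis run.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path


@dataclass
class Thresholds:
    """Tunable cutoffs of the analysis pipeline.

    hoogsteen_dmax : Å, heavy-atom donor-acceptor cutoff for Hoogsteen pairs
    channel_radius / channel_margin : Å, channel cylinder geometry
    leak_min_out : frames an ion must stay out before a leakage event counts
    expulsion_dist : Å, base-COM distance from tetrad centroid for expulsion
    event_min_frames : frames of persistent H-bond loss defining disruption
    twist_bin_width : degrees, histogram bin for twist distributions
    detection_window : frames averaged (after rigid alignment) to obtain
        the low-noise reference structure on which tetrads are detected
    """

    hoogsteen_dmax: float = 3.5
    channel_radius: float = 3.0
    channel_margin: float = 2.0
    leak_min_out: int = 10
    expulsion_dist: float = 8.0
    event_min_frames: int = 20
    twist_bin_width: float = 2.0
    detection_window: int = 20

    @classmethod
    def from_toml(cls, path: str | Path) -> "Thresholds":
        data = tomllib.loads(Path(path).read_text())
        data = data.get("thresholds", data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def to_toml(self, path: str | Path) -> Path:
        lines = ["[thresholds]"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        path = Path(path)
        path.write_text("\n".join(lines).replace("'", '"') + "\n")
        return path
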