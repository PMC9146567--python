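"""Channel-cation occupancy and leakage detection.

The ion channel of a G4 is modelled as a cylinder around the per-frame
tetrad axis: an ion is "in" the channel when its distance from the axis is
at most ``radius`` and its axial projection lies between the first and
last tetrad centroid extended by ``margin`` at both ends.  A leakage event
is an in -> out transition that persists for at least ``min_out``
consecutive frames (hysteresis against thermal flicker); re-entry, when it
happens, is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

from .structure import Trajectory
from .topology import TetradTopology, frame_axis

DEFAULT_CHANNEL_RADIUS = 3.0  # Å
DEFAULT_CHANNEL_MARGIN = 2.0  # Å
DEFAULT_MIN_OUT = 10          # frames


@dataclass
class ChannelState:
    """Per-frame, per-ion in/out flags plus the channel geometry used."""

    in_channel: np.ndarray          # (n_frames, n_ions) bool
    ion_indices: np.ndarray         # atom indices
    radius: float
    margin: float

    @property
    def n_frames(self) -> int:
        return self.in_channel.shape[0]

    @property
    def n_ions(self) -> int:
        return self.in_channel.shape[1]


@dataclass
class LeakageEvent:
    """One ion leaving the channel (and possibly returning)."""

    ion_index: int
    exit_frame: int
    reentry_frame: int | None
    dwell_out: int

    def __post_init__(self) -> None:
        if self.reentry_frame is not None and self.exit_frame >= self.reentry_frame:
            raise ValueError("exit must precede re-entry")


def channel_occupancy(
    traj: Trajectory,
    topology: TetradTopology,
    radius: float = DEFAULT_CHANNEL_RADIUS,
    margin: float = DEFAULT_CHANNEL_MARGIN,
    ions: np.ndarray | None = None,
) -> ChannelState:
    """Evaluate the cylinder criterion for every ion in every frame.

    The axis and axial bounds are recomputed per frame from the tracked
    tetrad membership, so occupancy is invariant under rigid motion.
    """
    model = traj.model
    ion_idx = model.ions if ions is None else np.asarray(ions, dtype=int)
    if len(ion_idx) == 0:
        warnings.warn("no ions present; channel state is empty")
        return ChannelState(np.zeros((traj.n_frames, 0), dtype=bool),
                            ion_idx, radius, margin)
    if len(topology.tetrads) < 2:
        raise ValueError("channel occupancy needs at least 2 tetrads")
    flags = np.zeros((traj.n_frames, len(ion_idx)), dtype=bool)
    for f in range(traj.n_frames):
        coords = traj.frames[f]
        axis, centroids = frame_axis(model, topology, coords)
        origin = centroids.mean(axis=0)
        proj = centroids @ axis
        lo, hi = proj.min() - margin, proj.max() + margin
        rel = coords[ion_idx] - origin
        axial = rel @ axis + origin @ axis
        radial = np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)
        flags[f] = (radial <= radius) & (axial >= lo) & (axial <= hi)
    return ChannelState(flags, ion_idx, radius, margin)


def detect_leakage(state: ChannelState, min_out: int = DEFAULT_MIN_OUT,
                   ) -> list[LeakageEvent]:
    """Leakage events: in -> out transitions persisting >= min_out frames."""
    if state.n_frames == 0:
        raise ValueError("channel state is empty")
    events: list[LeakageEvent] = []
    for k in range(state.n_ions):
        flags = state.in_channel[:, k]
        f = 0
        while f < len(flags):
            if f > 0 and flags[f - 1] and not flags[f]:
                # out-run starting here
                end = f
                while end < len(flags) and not flags[end]:
                    end += 1
                dwell = end - f
                if dwell >= min_out:
                    reentry = end if end < len(flags) else None
                    events.append(LeakageEvent(
                        ion_index=int(state.ion_indices[k]),
                        exit_frame=f, reentry_frame=reentry, dwell_out=dwell))
                f = end
            else:
                f += 1
    events.sort(key=lambda e: (e.exit_frame, e.ion_index))
    return events


def write_leakage_csv(events: list[LeakageEvent], path: str | Path) -> Path:
    """Export events as CSV (ion, exit frame, re-entry, dwell)."""
    path = Path(path)
    rows = [{
        "ion_index": e.ion_index,
        "exit_frame": e.exit_frame,
        "reentry_frame": "" if e.reentry_frame is None else e.reentry_frame,
        "dwell_out": e.dwell_out,
    } for e in events]
    pd.DataFrame(rows, columns=["ion_index", "exit_frame", "reentry_frame",
                                "dwell_out"]).to_csv(path, index=False,
                                                     lineterminator="\n")
    return path
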