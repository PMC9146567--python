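"""Distributions, destabilization events and the per-structure verdict.

"Stable" is operationalized through persistent-event logic: a structure is
destabilized when at least one disruption-class event — a tetrad guanine
losing both of its Hoogsteen bonds for a sustained stretch, or its outright
expulsion from the quartet — persists to the end of the trajectory.
Cation leakage is recorded as an event but flips the verdict only through
its structural consequence (a persistent tetrad disruption), matching the
observation that loss of a channel cation destabilizes a G4 only when the
quartet itself comes apart.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import circstd

from .config import Thresholds
from .geometry import (MetricSeries, aligned_mean_structure, angle_series,
                       com_distance_series, rmsd_series, twist_series)
from .ions import LeakageEvent, channel_occupancy, detect_leakage
from .structure import (Trajectory, nucleic_heavy_indices, tetrad_core_indices)
from .topology import (TetradTopology, detect_topology, base_com,
                       hoogsteen_distance_arrays)


def circular_difference(a: float, b: float) -> float:
    """Signed circular difference a - b wrapped to (-180, 180] degrees."""
    d = (a - b + 180.0) % 360.0 - 180.0
    return float(180.0 if d == -180.0 else d)


@dataclass
class TwistDistribution:
    """Circular histogram of a twist-angle series."""

    bin_edges: np.ndarray       # degrees, covering [-180, 180)
    density: np.ndarray         # normalized histogram
    mode: float                 # degrees, centre of the highest bin
    width: float                # circular standard deviation, degrees
    shift: float | None = None  # circular mode difference vs reference
    n: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)


def twist_distribution(
    series: MetricSeries | np.ndarray,
    reference: "TwistDistribution | None" = None,
    bin_width: float = 2.0,
) -> TwistDistribution:
    """Circular histogram, mode and width of a twist series (degrees).

    ``shift`` is the circular difference of modes against a reference
    distribution when one is supplied.
    """
    values = series.values if isinstance(series, MetricSeries) else \
        np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("empty twist series")
    wrapped = (values + 180.0) % 360.0 - 180.0
    n_bins = max(1, int(round(360.0 / bin_width)))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(wrapped, bins=edges, density=True)
    mode = float(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
    width = float(np.degrees(circstd(np.radians(wrapped))))
    shift = None if reference is None else circular_difference(mode, reference.mode)
    return TwistDistribution(bin_edges=edges, density=hist, mode=mode,
                             width=width, shift=shift, n=values.size)


# ---------------------------------------------------------------------------
# destabilization events
# ---------------------------------------------------------------------------

@dataclass
class DisruptionEvent:
    """A tetrad guanine losing both Hoogsteen bonds for a sustained stretch.

    ``kind`` is 'guanine_expulsion' when the detached guanine also moved
    beyond the expulsion distance from its tetrad centroid, otherwise
    'tetrad_disruption'.
    """

    kind: str
    resid: int
    tetrad_index: int
    onset_frame: int
    end_frame: int | None      # None when the event persists to the last frame
    max_com_distance: float

    @property
    def persists_to_end(self) -> bool:
        return self.end_frame is None


def detect_guanine_expulsion(
    traj: Trajectory,
    topology: TetradTopology,
    dist_thresh: float = 8.0,
    min_frames: int = 20,
    dmax: float = 3.5,
) -> list[DisruptionEvent]:
    """Detect persistent Hoogsteen detachment and guanine expulsion.

    Hoogsteen pairs of the tracked tetrads are re-evaluated every frame.
    A guanine is *detached* in a frame when neither of its two cycle bonds
    (to its donor-side and acceptor-side partner) is intact.  A run of
    detachment of at least ``min_frames`` frames is a tetrad-disruption
    event; it is promoted to a guanine-expulsion event when the base COM
    additionally moves more than ``dist_thresh`` beyond its attached
    baseline distance from the tetrad centroid (the centroid of the three
    remaining guanines) at some point during the run.  Measuring the
    excess over the attached baseline makes the threshold a displacement,
    independent of the quartet's intrinsic radius.
    """
    model = traj.model
    events: list[DisruptionEvent] = []
    n_frames = traj.n_frames
    # residue -> row lookup for the distance arrays, fixed topology
    resids0, _, _ = hoogsteen_distance_arrays(model, traj.frames[0])
    row = {int(r): k for k, r in enumerate(resids0)}
    detached = {}
    for t_idx, tet in enumerate(topology.tetrads):
        for g in tet.guanines:
            detached[(t_idx, g)] = np.zeros(n_frames, dtype=bool)
    com_dist = {key: np.zeros(n_frames) for key in detached}

    for f in range(n_frames):
        coords = traj.frames[f]
        _, d1, d2 = hoogsteen_distance_arrays(model, coords)
        intact = (d1 <= dmax) & (d2 <= dmax)
        for t_idx, tet in enumerate(topology.tetrads):
            cyc = tet.guanines
            for k, g in enumerate(cyc):
                nxt, prv = cyc[(k + 1) % 4], cyc[(k - 1) % 4]
                bond_out = intact[row[g], row[nxt]]
                bond_in = intact[row[prv], row[g]]
                if not bond_out and not bond_in:
                    detached[(t_idx, g)][f] = True
                others = [base_com(model, coords, h) for h in cyc if h != g]
                centroid = np.mean(others, axis=0)
                com_dist[(t_idx, g)][f] = np.linalg.norm(
                    base_com(model, coords, g) - centroid)

    for (t_idx, g), flags in detached.items():
        distances = com_dist[(t_idx, g)]
        attached = distances[~flags]
        baseline = float(np.median(attached)) if attached.size else \
            float(distances.min())
        f = 0
        while f < n_frames:
            if flags[f]:
                end = f
                while end < n_frames and flags[end]:
                    end += 1
                if end - f >= min_frames:
                    dmax_run = float(distances[f:end].max())
                    kind = ("guanine_expulsion"
                            if dmax_run - baseline > dist_thresh
                            else "tetrad_disruption")
                    events.append(DisruptionEvent(
                        kind=kind, resid=int(g), tetrad_index=t_idx,
                        onset_frame=f,
                        end_frame=None if end == n_frames else end,
                        max_com_distance=dmax_run))
                f = end
            else:
                f += 1
    events.sort(key=lambda e: (e.onset_frame, e.resid))
    return events


# ---------------------------------------------------------------------------
# report and verdict
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Aggregated metrics, events and the stability verdict for one structure."""

    label: str
    verdict: str                      # "stable" | "destabilized"
    n_frames: int
    events: list[dict] = field(default_factory=list)
    summaries: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @staticmethod
    def from_json(text: str) -> "StabilityReport":
        payload = json.loads(text)
        return StabilityReport(**payload)


def stability_verdict(
    disruption_events: list[DisruptionEvent],
    leakage_events: list[LeakageEvent],
    n_frames: int,
    label: str = "",
    summaries: dict | None = None,
) -> StabilityReport:
    """Combine events into the per-structure verdict.

    Destabilized iff at least one disruption-class event (tetrad disruption
    or guanine expulsion) persists to the final frame; cation leakage is
    recorded but does not flip the verdict on its own.
    """
    persistent = [e for e in disruption_events if e.persists_to_end]
    verdict = "destabilized" if persistent else "stable"
    events: list[dict] = []
    for e in disruption_events:
        events.append({
            "type": e.kind, "resid": e.resid, "tetrad_index": e.tetrad_index,
            "onset_frame": e.onset_frame, "end_frame": e.end_frame,
            "max_com_distance": round(e.max_com_distance, 3),
            "persists_to_end": e.persists_to_end,
        })
    for e in leakage_events:
        events.append({
            "type": "cation_leakage", "ion_index": e.ion_index,
            "exit_frame": e.exit_frame, "reentry_frame": e.reentry_frame,
            "dwell_out": e.dwell_out,
        })
    return StabilityReport(label=label, verdict=verdict, n_frames=n_frames,
                           events=events, summaries=summaries or {})


def analyze_trajectory(
    traj: Trajectory,
    label: str = "",
    thresholds: Thresholds | None = None,
    reference_twist: dict[str, TwistDistribution] | None = None,
    topology: TetradTopology | None = None,
) -> StabilityReport:
    """Full analysis pipeline for one conformational ensemble.

    Tetrad membership is detected once and tracked across all frames
    (only the geometry is re-evaluated per frame).  Unless a ``topology``
    is supplied, detection runs on the rigid-aligned mean of the first
    ``detection_window`` frames, a low-noise stand-in for the reference
    structure that is robust to thermal fluctuation of individual frames.
    The pipeline computes twist, COM-distance, guanine-angle and RMSD
    series; evaluates channel occupancy, leakage and disruption events;
    and issues the verdict.  ``reference_twist`` (per tetrad pair, keys
    like "twist_01") adds mode shifts against a native reference.
    """
    thr = thresholds or Thresholds()
    if topology is None:
        reference = aligned_mean_structure(traj, n_frames=thr.detection_window)
        topology = detect_topology(traj.model, reference,
                                   dmax=thr.hoogsteen_dmax,
                                   channel_radius=thr.channel_radius,
                                   channel_margin=thr.channel_margin)
    model = traj.model
    summaries: dict = {"n_tetrads": len(topology.tetrads)}

    core_idx = tetrad_core_indices(model, topology.tetrad_resids)
    whole_idx = nucleic_heavy_indices(model)
    core_rmsd = rmsd_series(traj, core_idx, name="rmsd_tetrads")
    whole_rmsd = rmsd_series(traj, whole_idx, name="rmsd_whole")
    summaries["rmsd_tetrads_p95"] = float(np.percentile(core_rmsd.values, 95))
    summaries["rmsd_tetrads_mean"] = float(core_rmsd.values.mean())
    summaries["rmsd_whole_mean"] = float(whole_rmsd.values.mean())

    n_t = len(topology.tetrads)
    pairs = [(i, i + 1) for i in range(n_t - 1)]
    if n_t > 2:
        pairs.append((0, n_t - 1))  # the terminal-tetrad twist
    twist_modes: dict[str, float] = {}
    for i, j in pairs:
        ts = twist_series(traj, topology, pair=(i, j))
        ref = None if reference_twist is None else reference_twist.get(ts.name)
        dist = twist_distribution(ts, reference=ref, bin_width=thr.twist_bin_width)
        twist_modes[ts.name] = dist.mode
        summaries[f"{ts.name}_mode"] = dist.mode
        summaries[f"{ts.name}_width"] = dist.width
        if dist.shift is not None:
            summaries[f"{ts.name}_shift"] = dist.shift
        cs = com_distance_series(traj, topology, pair=(i, j))
        summaries[f"{cs.name}_mean"] = float(cs.values.mean())
    for k in range(n_t):
        adj, opp = angle_series(traj, topology, tetrad_index=k)
        summaries[f"adjacent_angle_t{k}_mean"] = float(adj.values.mean())
        summaries[f"opposite_angle_t{k}_mean"] = float(opp.values.mean())

    if len(model.ions) and n_t >= 2:
        state = channel_occupancy(traj, topology, radius=thr.channel_radius,
                                  margin=thr.channel_margin)
        leaks = detect_leakage(state, min_out=thr.leak_min_out)
    else:
        leaks = []
    disruptions = detect_guanine_expulsion(
        traj, topology, dist_thresh=thr.expulsion_dist,
        min_frames=thr.event_min_frames, dmax=thr.hoogsteen_dmax)

    return stability_verdict(disruptions, leaks, traj.n_frames,
                             label=label, summaries=summaries)
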