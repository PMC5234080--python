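"""Trackable-trajectory extraction and comparison statistics.

A fluorescent particle is *trackable* in a frame when it carries at least
one alive fluorophore, sits inside the region of interest, and its nearest
visible neighbour is farther than an exclusion radius (default 0.5 um,
twice the diffraction limit).  Maximal runs of consecutive trackable frames
form trackable trajectories; the reason a trajectory ends (full
photobleaching, a close encounter, leaving the ROI, or the end of the
record) determines whether it can be used for subunit counting by
photobleaching steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .simulate import SimConfig, SimRecord, run_experiment

__all__ = [
    "Trajectory",
    "TrackingSummary",
    "DensitySeries",
    "EscapeEstimate",
    "trackable_mask",
    "extract_trajectories",
    "tracking_time_stats",
    "count_bleach_steps",
    "roi_density",
    "escape_probability",
    "parameter_sweep",
    "trajectories_dataframe",
]

END_REASONS = ("photobleached", "proximity", "roi_exit", "sim_end")


@dataclass
class Trajectory:
    """One maximal trackable segment of one particle."""

    particle_id: int
    start_frame: int  # simulation frame indices
    end_frame: int
    tau: float  # observation (camera frame) interval, s
    positions: np.ndarray  # (n_frames_in_segment, 2) um
    bleach_frames: np.ndarray  # frames (within the segment) of bleaching steps
    end_reason: str
    stride: int = 1  # simulation steps per observed frame

    @property
    def n_frames(self) -> int:
        """Observed (camera) frames in the segment."""
        return (self.end_frame - self.start_frame) // self.stride + 1

    @property
    def duration(self) -> float:
        """Duration in seconds; an n-frame segment lasts n * tau."""
        return self.n_frames * self.tau

    @property
    def n_bleach_steps(self) -> int:
        return len(self.bleach_frames)


@dataclass
class TrackingSummary:
    """Per-cell tracking statistics of one simulated experiment."""

    n_trajectories: int
    mean_duration: float
    sem_duration: float
    threshold_counts: dict  # duration threshold (s) -> count of longer trajectories
    bleach_step_hist: dict  # steps -> count, over photobleach-terminated trajectories
    n_photobleached: int
    end_reason_counts: dict

    @property
    def n_two_step(self) -> int:
        return self.bleach_step_hist.get(2, 0)

    @property
    def two_step_fraction(self) -> float:
        """Fraction of photobleach-terminated trajectories with two steps."""
        if self.n_photobleached == 0:
            return math.nan
        return self.n_two_step / self.n_photobleached

    @property
    def two_step_fraction_all(self) -> float:
        """Two-step trajectories as a fraction of all trajectories."""
        if self.n_trajectories == 0:
            return math.nan
        return self.n_two_step / self.n_trajectories

    def to_dict(self) -> dict:
        return {
            "n_trajectories": self.n_trajectories,
            "mean_duration_s": self.mean_duration,
            "sem_duration_s": self.sem_duration,
            "threshold_counts": {str(k): v for k, v in self.threshold_counts.items()},
            "bleach_step_hist": {str(k): v for k, v in self.bleach_step_hist.items()},
            "n_photobleached": self.n_photobleached,
            "n_two_step": self.n_two_step,
            "two_step_fraction": self.two_step_fraction,
            "two_step_fraction_all": self.two_step_fraction_all,
            "end_reason_counts": self.end_reason_counts,
        }


@dataclass
class DensitySeries:
    """Alive-spot density inside the ROI over time (spots per um^2)."""

    times: np.ndarray
    density: np.ndarray

    def mean_between(self, t0: float, t1: float) -> float:
        sel = (self.times >= t0) & (self.times <= t1)
        return float(self.density[sel].mean())

    def at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.density[i])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "density_per_um2": self.density})


@dataclass
class EscapeEstimate:
    """Empirical estimate of the gate escape probability."""

    probability: float
    n_escaped: int
    n_presented: int


def trackable_mask(
    positions: np.ndarray,
    n_alive: np.ndarray,
    roi_center: tuple[float, float],
    roi_radius: float,
    exclusion_radius: float = 0.5,
    visible: np.ndarray | None = None,
) -> np.ndarray:
    """Per-particle trackability for one frame of particle data.

    A particle is trackable when it has >= 1 alive fluorophore, lies inside
    the ROI disc, and every *visible* particle other than itself is farther
    than ``exclusion_radius`` away.  ``visible`` marks the rows that count
    as interfering neighbours (default: every row with alive fluorophores).
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n_alive = np.asarray(n_alive)
    alive = n_alive > 0
    if visible is None:
        visible = alive
    d2 = (positions[:, 0] - roi_center[0]) ** 2 + (positions[:, 1] - roi_center[1]) ** 2
    cand = alive & (d2 <= roi_radius**2)
    out = np.zeros(positions.shape[0], dtype=bool)
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return out
    vis_xy = positions[visible]
    if vis_xy.shape[0] <= 1:
        out[idx] = True
        return out
    tree = cKDTree(vis_xy)
    dist, _ = tree.query(positions[idx], k=2)
    # Column 0 is the particle itself (candidates are always visible);
    # column 1 is the nearest true neighbour.
    out[idx] = dist[:, 1] > exclusion_radius
    return out


def _dead_frames(record: SimRecord) -> dict:
    """Frame at which each fully bleached particle lost its last fluorophore."""
    events = record.bleach_events
    m = record.config.oligomer_size
    if events.shape[0] == 0:
        return {}
    order = np.lexsort((events[:, 0], events[:, 1]))
    pids = events[order, 1]
    frames = events[order, 0]
    boundaries = np.flatnonzero(np.diff(pids)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [pids.size]])
    dead = {}
    for s, e in zip(starts, ends):
        if e - s == m:
            dead[int(pids[s])] = int(frames[e - 1])
    return dead


DEFAULT_FRAME_INTERVAL = 0.05
"""Camera frame interval of the reference imaging protocol (20 Hz), s."""


def extract_trajectories(
    record: SimRecord,
    exclusion_radius: float = 0.5,
    neighbor_visibility: str = "illuminated",
    frame_interval: float | None = DEFAULT_FRAME_INTERVAL,
) -> list[Trajectory]:
    """Segment a simulation record into maximal trackable trajectories.

    ``neighbor_visibility`` selects which particles count as interfering
    neighbours: ``"illuminated"`` (default) counts only alive particles that
    are actually excited — everything in whole-cell illumination, only the
    ROI disc when the TIRF beam is restricted to it — while ``"all_alive"``
    counts every unbleached particle regardless of illumination.

    ``frame_interval`` is the camera frame time: trackability is assessed
    at camera frames (every ``round(frame_interval / tau)``-th simulation
    step, the 20 Hz imaging rate by default), since interruptions shorter
    than a frame are invisible to the camera.  Pass ``None`` to analyse
    every simulation step.

    The end reason is the first condition violated after the last trackable
    frame: full photobleaching, a too-close neighbour (``proximity``),
    leaving the ROI (``roi_exit``), or the end of the record (``sim_end``).
    A terminal bleaching event (the one that ends the trajectory) is
    attributed to the trajectory's final frame.
    """
    if not record.frame_ids:
        raise ValueError("record has no stored frames (store_frames=False?)")
    cfg = record.config
    tau = cfg.resolved_tau()
    stride = 1 if frame_interval is None else max(1, int(round(frame_interval / tau)))
    center = cfg.center
    roi_r = cfg.roi_radius
    roi_r2 = roi_r**2
    mode = cfg.resolved_tirf().mode
    restrict_visible = neighbor_visibility == "illuminated" and mode == "roi_only"

    # Particles can only be observed (and tracked) while the imaging beam
    # is on; frames during the dark delay are invisible to the camera.
    t_on, t_off = cfg.resolved_schedule().tirf_on_interval
    f_lo = int(math.ceil(t_on / tau - 1e-9))
    f_hi = min(record.n_frames - 1, int(math.floor(t_off / tau + 1e-9)))

    track_pids, track_frames, track_xy = [], [], []
    for f in range(f_lo, f_hi + 1, stride):
        ids = record.frame_ids[f]
        if ids.size == 0:
            continue
        xy = record.frame_xy[f].astype(float)
        d2 = (xy[:, 0] - center[0]) ** 2 + (xy[:, 1] - center[1]) ** 2
        cand = d2 <= roi_r2
        n_cand = int(cand.sum())
        if n_cand == 0:
            continue
        visible = cand if restrict_visible else np.ones(ids.size, dtype=bool)
        vis_xy = xy[visible]
        if vis_xy.shape[0] <= 1:
            ok = cand
        else:
            tree = cKDTree(vis_xy)
            dist, _ = tree.query(xy[cand], k=2)
            ok = np.zeros(ids.size, dtype=bool)
            ok[np.flatnonzero(cand)] = dist[:, 1] > exclusion_radius
        sel = np.flatnonzero(ok)
        if sel.size:
            track_pids.append(ids[sel].astype(np.int64))
            track_frames.append(np.full(sel.size, f, dtype=np.int64))
            track_xy.append(xy[sel])

    if not track_pids:
        return []
    pids = np.concatenate(track_pids)
    frames = np.concatenate(track_frames)
    xys = np.concatenate(track_xy)
    order = np.lexsort((frames, pids))
    pids, frames, xys = pids[order], frames[order], xys[order]
    new_seg = np.ones(pids.size, dtype=bool)
    new_seg[1:] = (pids[1:] != pids[:-1]) | (frames[1:] != frames[:-1] + stride)
    starts = np.flatnonzero(new_seg)
    ends = np.concatenate([starts[1:], [pids.size]])

    dead = _dead_frames(record)
    events = record.bleach_events
    if events.shape[0]:
        ev_order = np.lexsort((events[:, 0], events[:, 1]))
        ev_pids = events[ev_order, 1]
        ev_frames = events[ev_order, 0]
    else:
        ev_pids = np.empty(0, dtype=np.int64)
        ev_frames = np.empty(0, dtype=np.int64)
    last_frame = f_hi

    trajectories = []
    for s, e in zip(starts, ends):
        pid = int(pids[s])
        f0, f1 = int(frames[s]), int(frames[e - 1])
        death = dead.get(pid)
        f_next = f1 + stride

        if f_next > last_frame:
            reason = "sim_end"
        elif death is not None and f1 < death <= f_next:
            reason = "photobleached"
        else:
            nxt_ids = record.frame_ids[f_next]
            j = np.searchsorted(nxt_ids, pid)
            if j < nxt_ids.size and nxt_ids[j] == pid:
                x, y = record.frame_xy[f_next][j]
                d2 = (float(x) - center[0]) ** 2 + (float(y) - center[1]) ** 2
                reason = "proximity" if d2 <= roi_r2 else "roi_exit"
            else:
                # alive (not fully bleached) but outside the recorded region
                reason = "roi_exit"
        lo = np.searchsorted(ev_pids, pid, side="left")
        hi = np.searchsorted(ev_pids, pid, side="right")
        seg_events = ev_frames[lo:hi]
        ev_hi = f_next if reason == "photobleached" else f1
        seg_events = seg_events[(seg_events > f0 - stride) & (seg_events <= ev_hi)]
        trajectories.append(
            Trajectory(
                particle_id=pid,
                start_frame=f0,
                end_frame=f1,
                tau=tau * stride,
                positions=xys[s:e],
                bleach_frames=np.minimum(seg_events, f1),
                end_reason=reason,
                stride=stride,
            )
        )
    return trajectories


def count_bleach_steps(traj: Trajectory) -> tuple[int, bool]:
    """Photobleaching steps within a trajectory and its counting eligibility.

    Only trajectories terminated by full photobleaching can be used for
    subunit counting — a segment cut short by a close encounter or ROI exit
    may hide further steps.
    """
    return traj.n_bleach_steps, traj.end_reason == "photobleached"


def tracking_time_stats(
    trajectories: list[Trajectory],
    thresholds: tuple[float, ...] = (3.0,),
) -> TrackingSummary:
    """Mean duration, long-trajectory counts and bleach-step histogram."""
    n = len(trajectories)
    if n == 0:
        return TrackingSummary(
            n_trajectories=0,
            mean_duration=math.nan,
            sem_duration=math.nan,
            threshold_counts={float(t): 0 for t in thresholds},
            bleach_step_hist={},
            n_photobleached=0,
            end_reason_counts={r: 0 for r in END_REASONS},
        )
    durations = np.array([t.duration for t in trajectories])
    reasons = [t.end_reason for t in trajectories]
    hist: dict[int, int] = {}
    n_bleached = 0
    for t in trajectories:
        steps, eligible = count_bleach_steps(t)
        if eligible:
            n_bleached += 1
            hist[steps] = hist.get(steps, 0) + 1
    sem = float(durations.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return TrackingSummary(
        n_trajectories=n,
        mean_duration=float(durations.mean()),
        sem_duration=sem,
        threshold_counts={float(t): int((durations > t).sum()) for t in thresholds},
        bleach_step_hist=dict(sorted(hist.items())),
        n_photobleached=n_bleached,
        end_reason_counts={r: reasons.count(r) for r in END_REASONS},
    )


def roi_density(record: SimRecord) -> DensitySeries:
    """Alive-spot density inside the ROI, frame by frame.

    The single-molecule detection limit for comparison is about 1 fluorescent
    spot per um^2.
    """
    return DensitySeries(
        times=record.times.copy(),
        density=record.roi_alive.astype(float) / record.roi_area(),
    )


def escape_probability(record: SimRecord) -> EscapeEstimate:
    """Empirical probability that a particle crosses the gate ring and
    survives the sweep that should have caught it.

    A *crossing* is a pair of consecutive frames taking an alive particle
    from outside the ring (``d > R``) to inside (``d <= R``).  A crossing
    *escapes* when the particle is still fluorescent after the next gate
    sweep; crossings with no subsequent sweep in the record are not counted.
    With no observed crossings the probability is reported as 0 alongside
    the zero count.
    """
    cfg = record.config
    gate = cfg.resolved_gate()
    if gate is None:
        raise ValueError("record has no gate; escape probability is undefined for TOCCSL")
    if not record.frame_ids:
        raise ValueError("record has no stored frames")
    if record.record_radius <= gate.ring_radius:
        raise ValueError("record_radius must extend beyond the gate ring")
    center = cfg.center
    R = gate.ring_radius
    tau = cfg.resolved_tau()
    gate_frames = np.array(
        sorted(
            int(math.ceil(t / tau - 1e-9))
            for t in cfg.resolved_schedule().gate_event_times
        ),
        dtype=np.int64,
    )
    if gate_frames.size == 0:
        raise ValueError("schedule has no gate events")

    def radii(f):
        xy = record.frame_xy[f]
        return np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1])

    crossings: list[tuple[int, int]] = []  # (pid, frame of arrival inside)
    prev_ids = record.frame_ids[0]
    prev_r = radii(0)
    for f in range(1, record.n_frames):
        ids = record.frame_ids[f]
        r = radii(f)
        common, ia, ib = np.intersect1d(prev_ids, ids, return_indices=True)
        if common.size:
            crossed = (prev_r[ia] > R) & (r[ib] <= R)
            crossings.extend((int(p), f) for p in common[crossed])
        prev_ids, prev_r = ids, r

    dead = _dead_frames(record)
    n_escaped = 0
    n_presented = 0
    for pid, f in crossings:
        j = np.searchsorted(gate_frames, f, side="left")
        if j >= gate_frames.size:
            continue  # no sweep left to test the crosser against
        next_gate = int(gate_frames[j])
        n_presented += 1
        death = dead.get(pid)
        if death is None or death > next_gate:
            n_escaped += 1

    prob = n_escaped / n_presented if n_presented else 0.0
    return EscapeEstimate(probability=prob, n_escaped=n_escaped, n_presented=n_presented)


SWEEP_AXES = ("gate_frequency", "roi_radius", "photon_flux")


def parameter_sweep(
    base: SimConfig,
    axis: str,
    values,
    seed_policy: str = "shared",
    store_frames: bool = False,
):
    """Run one simulation per value of a protocol parameter.

    ``axis`` is one of ``gate_frequency``, ``roi_radius`` or ``photon_flux``.
    Derived fields (TIRF disc, gate beam, schedule) are rebuilt for each
    value.  ``seed_policy`` is ``"shared"`` (same seed for every run, for
    paired comparisons) or ``"independent"`` (seed + index).  Returns
    ``(values, times, density_matrix)`` where row i is the ROI density
    series of run i.
    """
    values = list(values)
    if not values:
        raise ValueError("values must be nonempty")
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    times = None
    rows = []
    for i, v in enumerate(values):
        overrides = {"tirf": None, "gate": None, "schedule": None, "store_frames": store_frames}
        if axis == "gate_frequency":
            overrides["gate_frequency"] = v
        elif axis == "roi_radius":
            overrides["roi_radius"] = v
            overrides["record_radius"] = None
        else:
            overrides["tirf_flux"] = v
        if seed_policy == "independent":
            overrides["seed"] = base.seed + i
        cfg = replace(base, **overrides)
        rec = run_experiment(cfg)
        series = roi_density(rec)
        if times is None:
            times = series.times
        rows.append(series.density)
    return np.asarray(values, dtype=float), times, np.vstack(rows)


def trajectories_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table of trajectory positions for CSV export."""
    rows = []
    for tid, t in enumerate(trajectories):
        fr = np.arange(t.start_frame, t.end_frame + 1, t.stride)
        rows.append(
            pd.DataFrame(
                {
                    "trajectory_id": tid,
                    "particle_id": t.particle_id,
                    "frame": fr,
                    "time_s": fr * t.tau / t.stride,
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["trajectory_id", "particle_id", "frame", "time_s", "x_um", "y_um"]
        )
    return pd.concat(rows, ignore_index=True)
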