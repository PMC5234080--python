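import math
from dataclasses import replace

import numpy as np
import pytest

from photogate.illumination import GateBeam
from photogate.simulate import (
    SimConfig,
    SimRecord,
    photogate_config,
    run_experiment,
    toccsl_config,
)
from photogate.tracking import (
    DensitySeries,
    count_bleach_steps,
    escape_probability,
    extract_trajectories,
    parameter_sweep,
    roi_density,
    trackable_mask,
    tracking_time_stats,
    trajectories_dataframe,
)


def brute_force_mask(positions, n_alive, center, roi_radius, excl, visible=None):
    """O(n^2) oracle for the trackability rule."""
    n = len(positions)
    alive = np.asarray(n_alive) > 0
    vis = alive if visible is None else np.asarray(visible)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        if not alive[i]:
            continue
        if np.hypot(*(np.asarray(positions[i]) - center)) > roi_radius:
            continue
        ok = True
        for j in range(n):
            if j == i or not vis[j]:
                continue
            if np.hypot(*(np.asarray(positions[i]) - positions[j])) <= excl:
                ok = False
                break
        out[i] = ok
    return out


def make_record(config, frames, bleach_events=()):
    """Assemble a synthetic SimRecord from scripted per-frame states.

    ``frames`` is a list of dicts: particle id -> (x, y, n_alive).
    """
    tau = config.resolved_tau()
    frame_ids, frame_xy, frame_nal, roi_alive = [], [], [], []
    cx, cy = config.center
    for state in frames:
        ids = np.array(sorted(state), dtype=np.int32)
        xy = np.array([state[i][:2] for i in ids], dtype=np.float32).reshape(-1, 2)
        nal = np.array([state[i][2] for i in ids], dtype=np.uint8)
        keep = nal > 0
        frame_ids.append(ids[keep])
        frame_xy.append(xy[keep])
        frame_nal.append(nal[keep])
        d2 = (xy[keep, 0] - cx) ** 2 + (xy[keep, 1] - cy) ** 2
        roi_alive.append(int((d2 <= config.roi_radius**2).sum()))
    ev = (
        np.array(bleach_events, dtype=np.int64).reshape(-1, 3)
        if len(bleach_events)
        else np.empty((0, 3), dtype=np.int64)
    )
    return SimRecord(
        config=config,
        times=np.arange(len(frames)) * tau,
        frame_ids=frame_ids,
        frame_xy=frame_xy,
        frame_nalive=frame_nal,
        bleach_events=ev,
        roi_alive=np.array(roi_alive),
        n_particles=max((max(f) for f in frames if f), default=-1) + 1,
        record_radius=config.resolved_record_radius(),
    )


CFG = SimConfig(cell_size=20.0, density=1.0, roi_radius=6.0, tau=0.05, seed=0,
                tirf_mode="whole_cell")


class TestTrackableMask:
    def test_lone_particle_trackable(self):
        m = trackable_mask(np.array([[10.0, 10.0]]), np.array([2]), (10, 10), 6.0)
        assert m.tolist() == [True]

    def test_close_pair_untrackable(self):
        pos = np.array([[10.0, 10.0], [10.4, 10.0]])
        m = trackable_mask(pos, np.array([1, 1]), (10, 10), 6.0)
        assert m.tolist() == [False, False]

    def test_pair_beyond_exclusion_trackable(self):
        pos = np.array([[10.0, 10.0], [10.6, 10.0]])
        m = trackable_mask(pos, np.array([1, 1]), (10, 10), 6.0)
        assert m.tolist() == [True, True]

    def test_bleached_neighbour_ignored(self):
        pos = np.array([[10.0, 10.0], [10.2, 10.0]])
        m = trackable_mask(pos, np.array([1, 0]), (10, 10), 6.0)
        assert m.tolist() == [True, False]

    def test_outside_roi_not_trackable(self):
        m = trackable_mask(np.array([[19.0, 10.0]]), np.array([1]), (10, 10), 6.0)
        assert m.tolist() == [False]

    def test_matches_brute_force_on_random_configurations(self, rng):
        for _ in range(20):
            n = rng.integers(2, 40)
            pos = rng.uniform(4, 16, size=(n, 2))
            nal = rng.integers(0, 3, size=n)
            got = trackable_mask(pos, nal, (10, 10), 5.0, 0.7)
            ref = brute_force_mask(pos, nal, (10, 10), 5.0, 0.7)
            assert np.array_equal(got, ref)


class TestExtractTrajectories:
    def test_always_trackable_particle_ends_with_sim_end(self):
        frames = [{0: (10.0, 10.0, 2)} for _ in range(5)]
        trajs = extract_trajectories(make_record(CFG, frames), frame_interval=None)
        assert len(trajs) == 1
        t = trajs[0]
        assert (t.start_frame, t.end_frame, t.end_reason) == (0, 4, "sim_end")
        assert t.duration == pytest.approx(5 * 0.05)

    def test_alternating_visibility_gives_single_frame_segments(self):
        frames = []
        for f in range(6):
            if f % 2 == 0:
                frames.append({0: (10.0, 10.0, 1)})
            else:  # neighbour too close on odd frames
                frames.append({0: (10.0, 10.0, 1), 1: (10.2, 10.0, 1)})
        trajs = extract_trajectories(make_record(CFG, frames), frame_interval=None)
        mine = [t for t in trajs if t.particle_id == 0]
        assert len(mine) == 3
        assert all(t.n_frames == 1 for t in mine)
        assert all(t.end_reason == "proximity" for t in mine[:-1])

    def test_roi_exit_reason(self):
        frames = [
            {0: (10.0, 10.0, 1)},
            {0: (12.0, 10.0, 1)},
            {0: (10 + 6.2, 10.0, 1)},  # outside 6 um ROI but inside record
        ]
        cfg = replace(CFG, record_radius=10.0)
        trajs = extract_trajectories(make_record(cfg, frames), frame_interval=None)
        assert len(trajs) == 1
        assert trajs[0].end_reason == "roi_exit"

    def test_photobleach_reason_and_steps(self):
        frames = [
            {0: (10.0, 10.0, 2)},
            {0: (10.1, 10.0, 1)},  # one step at frame 1
            {0: (10.2, 10.0, 0)},  # second step at frame 2 ends the track
        ]
        ev = [(1, 0, 0), (2, 0, 1)]
        trajs = extract_trajectories(make_record(CFG, frames, ev), frame_interval=None)
        assert len(trajs) == 1
        t = trajs[0]
        assert t.end_reason == "photobleached"
        assert (t.start_frame, t.end_frame) == (0, 1)
        steps, eligible = count_bleach_steps(t)
        assert steps == 2 and eligible

    def test_scripted_step_counts_match_ground_truth(self):
        # two dimers: one fully bleaches in-track, one exits the ROI
        frames = []
        for f in range(4):
            s = {}
            s[0] = (8.0, 10.0, 2 if f < 2 else (1 if f < 3 else 0))
            s[1] = (12.0, 10.0 + (3.5 * f if f >= 2 else 0), 2)
            frames.append(s)
        ev = [(2, 0, 0), (3, 0, 1)]
        cfg = replace(CFG, record_radius=12.0)
        trajs = extract_trajectories(make_record(cfg, frames, ev), frame_interval=None)
        by_pid = {t.particle_id: t for t in trajs}
        assert by_pid[0].end_reason == "photobleached"
        assert count_bleach_steps(by_pid[0]) == (2, True)
        assert by_pid[1].end_reason == "roi_exit"
        assert count_bleach_steps(by_pid[1])[1] is False

    def test_segmentation_matches_per_frame_oracle(self, rng, small_toccsl):
        """Segment boundaries agree with a brute-force per-frame scan."""
        rec = run_experiment(small_toccsl)
        trajs = extract_trajectories(rec, frame_interval=None)
        # oracle: recompute trackable sets frame by frame
        segs = {}
        open_seg = {}
        for f in range(rec.n_frames):
            ids = rec.frame_ids[f]
            mask = brute_force_mask(
                rec.frame_xy[f].astype(float),
                rec.frame_nalive[f],
                small_toccsl.center,
                small_toccsl.roi_radius,
                0.5,
            )
            trackable = set(ids[mask].tolist())
            for pid in list(open_seg):
                if pid not in trackable:
                    segs.setdefault(pid, []).append(open_seg.pop(pid) + (f - 1,))
            for pid in trackable:
                if pid not in open_seg:
                    open_seg[pid] = (f,)
        for pid, start in open_seg.items():
            segs.setdefault(pid, []).append(start + (rec.n_frames - 1,))
        expected = sorted(
            (pid, s, e) for pid, lst in segs.items() for s, e in lst
        )
        got = sorted((t.particle_id, t.start_frame, t.end_frame) for t in trajs)
        assert got == expected

    def test_every_trajectory_frame_is_trackable(self, small_photogate):
        """Re-check invariant: each frame of each trajectory passes the rule."""
        rec = run_experiment(small_photogate)
        trajs = extract_trajectories(rec, frame_interval=None)
        t_on = small_photogate.dark_delay
        tau = small_photogate.resolved_tau()
        for t in trajs[:50]:
            assert t.start_frame * tau >= t_on - 1e-9
            f = t.start_frame
            ids = rec.frame_ids[f]
            xy = rec.frame_xy[f].astype(float)
            vis_d2 = (xy[:, 0] - 6.0) ** 2 + (xy[:, 1] - 6.0) ** 2
            vis = vis_d2 <= small_photogate.roi_radius**2
            mask = brute_force_mask(
                xy, rec.frame_nalive[f], (6.0, 6.0),
                small_photogate.roi_radius, 0.5, visible=vis,
            )
            assert mask[np.searchsorted(ids, t.particle_id)]


class TestTrackingTimeStats:
    def test_single_trajectory_mean(self):
        frames = [{0: (10.0, 10.0, 1)} for _ in range(10)]
        trajs = extract_trajectories(make_record(CFG, frames), frame_interval=None)
        s = tracking_time_stats(trajs, thresholds=(0.3,))
        assert s.n_trajectories == 1
        assert s.mean_duration == pytest.approx(10 * 0.05)
        assert s.threshold_counts[0.3] == 1

    def test_empty_input(self):
        s = tracking_time_stats([], thresholds=(3.0,))
        assert s.n_trajectories == 0
        assert math.isnan(s.mean_duration)
        assert s.threshold_counts[3.0] == 0

    def test_end_reasons_partition_trajectories(self, small_photogate):
        rec = run_experiment(small_photogate)
        trajs = extract_trajectories(rec)
        s = tracking_time_stats(trajs)
        assert sum(s.end_reason_counts.values()) == s.n_trajectories

    def test_photogate_tracks_longer_than_toccsl(self):
        """Gating must (stochastically) lengthen mean trackable time."""
        means = {"pg": [], "toc": []}
        for seed in range(3):
            pg = photogate_config(
                cell_size=16.0, density=20.0, D=0.1, duration=8.0,
                roi_radius=4.0, gate_frequency=1.0, dark_delay=1.0, seed=seed,
            )
            toc = toccsl_config(
                cell_size=16.0, density=20.0, D=0.1, duration=8.0,
                roi_radius=4.0, seed=seed,
            )
            for key, cfg in (("pg", pg), ("toc", toc)):
                trajs = extract_trajectories(run_experiment(cfg))
                means[key].append(tracking_time_stats(trajs).mean_duration)
        assert np.mean(means["pg"]) > np.mean(means["toc"])


class TestRoiDensity:
    def test_all_bleached_gives_zero(self):
        frames = [{0: (10.0, 10.0, 0)} for _ in range(3)]
        d = roi_density(make_record(CFG, frames))
        assert np.all(d.density == 0.0)

    def test_density_is_count_over_area(self):
        frames = [{i: (9.0 + i, 10.0, 1) for i in range(3)}]
        d = roi_density(make_record(CFG, frames))
        assert d.density[0] == pytest.approx(3 / (math.pi * 36.0))

    def test_mean_between(self):
        s = DensitySeries(times=np.arange(5.0), density=np.array([0, 1, 2, 3, 4.0]))
        assert s.mean_between(1.0, 3.0) == pytest.approx(2.0)


class TestEscapeProbability:
    def _run(self, amplitude, seed=0):
        beam = GateBeam(
            amplitude=amplitude, width=0.42, ring_radius=3.0, period=0.5,
            center=(6.0, 6.0),
        )
        cfg = photogate_config(
            cell_size=12.0, density=10.0, D=0.3, duration=6.0, roi_radius=3.0,
            gate=beam, gate_frequency=None, dark_delay=0.5, seed=seed,
            record_radius=4.5,
        )
        return run_experiment(cfg)

    def test_toccsl_record_rejected(self, small_toccsl):
        rec = run_experiment(small_toccsl)
        with pytest.raises(ValueError):
            escape_probability(rec)

    def test_weak_gate_lets_everything_through(self):
        est = escape_probability(self._run(amplitude=1e-6))
        assert est.n_presented > 0
        assert est.probability == pytest.approx(1.0)

    def test_overwhelming_gate_blocks_crossers(self):
        est = escape_probability(self._run(amplitude=1e12))
        assert est.probability < 0.2

    def test_monotone_in_amplitude(self):
        amps = [1e2, 1e5, 5e5, 5e6, 1e12]
        probs = [
            np.mean([escape_probability(self._run(a, seed=s)).probability
                     for s in range(2)])
            for a in amps
        ]
        assert all(b <= a + 0.05 for a, b in zip(probs, probs[1:]))

    def test_requires_wide_enough_record(self):
        rec = self._run(1e5)
        object.__setattr__(rec, "record_radius", 2.5)
        with pytest.raises(ValueError):
            escape_probability(rec)


class TestParameterSweep:
    BASE = dict(cell_size=12.0, density=8.0, D=0.2, duration=4.0, roi_radius=3.0,
                dark_delay=0.5)

    def test_single_value_equals_direct_run(self):
        base = photogate_config(**self.BASE, gate_frequency=1.0, seed=4)
        vals, times, dens = parameter_sweep(base, "photon_flux", [2000.0])
        direct = roi_density(
            run_experiment(replace(base, store_frames=False))
        )
        assert np.allclose(dens[0], direct.density)

    def test_invalid_axis_rejected(self):
        base = photogate_config(**self.BASE, gate_frequency=1.0)
        with pytest.raises(ValueError):
            parameter_sweep(base, "bogus", [1.0])
        with pytest.raises(ValueError):
            parameter_sweep(base, "photon_flux", [])

    def test_density_non_increasing_in_gate_frequency(self):
        base = photogate_config(**self.BASE, seed=9)
        vals, times, dens = parameter_sweep(
            base, "gate_frequency", [0.25, 1.0, 4.0]
        )
        at_end = dens[:, -40:].mean(axis=1)
        assert at_end[0] >= at_end[1] - 0.05
        assert at_end[1] >= at_end[2] - 0.05


class TestExports:
    def test_trajectory_dataframe_roundtrip(self, small_photogate):
        rec = run_experiment(small_photogate)
        trajs = extract_trajectories(rec)
        df = trajectories_dataframe(trajs)
        assert set(df.columns) == {
            "trajectory_id", "particle_id", "frame", "time_s", "x_um", "y_um"
        }
        if len(trajs):
            assert df.groupby("trajectory_id").size().iloc[0] == trajs[0].n_frames

    def test_record_save(self, tmp_path, small_toccsl):
        rec = run_experiment(replace(small_toccsl, duration=1.0))
        rec.save(tmp_path)
        assert (tmp_path / "record_frames.csv").exists()
        assert (tmp_path / "record_bleach_events.csv").exists()
        assert (tmp_path / "record_config.json").exists()
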