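"""Experiment presets for the simulated gated-tracking comparisons.

Each preset bundles one standard condition of the gated-vs-ungated
comparison: matched gated and gate-free runs of dimeric particles, the
photon-flux / gate-frequency / ROI-radius sweeps, and the corresponding
statistics to emit.  Presets are full-scale by default (40 x 40 um cell,
50 particles per um^2, 80 s); pass overrides (duration, cell_size, density,
...) to run them at reduced scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import dump_config
from .simulate import SimConfig, photogate_config, toccsl_config, run_experiment
from .tracking import (
    extract_trajectories,
    parameter_sweep,
    roi_density,
    tracking_time_stats,
    trajectories_dataframe,
)

log = logging.getLogger("photogate")

__all__ = ["ExperimentPreset", "PRESETS", "run_preset"]


@dataclass(frozen=True)
class ExperimentPreset:
    """A named experiment: config overrides plus an analysis plan."""

    name: str
    description: str
    overrides: dict
    paired_toccsl: bool = True  # also run the matched gate-free experiment
    analysis: tuple[str, ...] = ("tracking", "density")
    sweep_axis: str | None = None
    sweep_values: tuple[float, ...] = ()
    extra_conditions: tuple[dict, ...] = ()  # e.g. second diffusion constant


_FIG5_BASE = {"D": 0.1, "gate_frequency": 0.5, "roi_radius": 7.0, "oligomer_size": 2}

PRESETS: dict[str, ExperimentPreset] = {
    p.name: p
    for p in [
        ExperimentPreset(
            name="fig5a-slow",
            description="Tracking-time comparison, D=0.1 um^2/s, 0.5 Hz gate, 14 um ROI",
            overrides=dict(_FIG5_BASE),
        ),
        ExperimentPreset(
            name="fig5a-fast",
            description="Tracking-time comparison, D=0.5 um^2/s, 3 Hz gate",
            overrides={**_FIG5_BASE, "D": 0.5, "gate_frequency": 3.0},
        ),
        ExperimentPreset(
            name="fig5b",
            description="One- and two-step bleaching counts for dimers, D=0.1 um^2/s",
            overrides=dict(_FIG5_BASE),
            analysis=("tracking", "steps"),
        ),
        ExperimentPreset(
            name="fig5c",
            description="ROI density vs TIRF photon flux (0 to 12,000 /s)",
            overrides=dict(_FIG5_BASE),
            analysis=("density",),
            sweep_axis="photon_flux",
            sweep_values=(0, 1500, 3000, 6000, 9000, 12000),
        ),
        ExperimentPreset(
            name="fig5d",
            description="Typical density time courses at 1,500 photons/s, 0.5 Hz gate",
            overrides={**_FIG5_BASE, "tirf_flux": 1500.0},
            analysis=("density",),
        ),
        ExperimentPreset(
            name="fig5e",
            description="ROI density 30 s after bleaching vs gate frequency, D=0.1 and 1",
            overrides=dict(_FIG5_BASE),
            paired_toccsl=False,
            analysis=("density",),
            sweep_axis="gate_frequency",
            sweep_values=(0.2, 0.5, 1.0, 2.0, 3.0),
            extra_conditions=({"D": 1.0},),
        ),
        ExperimentPreset(
            name="fig5f",
            description="ROI density time courses vs ROI radius",
            overrides=dict(_FIG5_BASE),
            analysis=("density",),
            sweep_axis="roi_radius",
            sweep_values=(3.0, 5.0, 7.0, 9.0),
        ),
    ]
}


def _build_config(preset: ExperimentPreset, gated: bool, seed: int, extra: dict) -> SimConfig:
    kw = {**preset.overrides, **extra, "seed": seed}
    if gated:
        return photogate_config(**kw)
    kw.pop("gate_frequency", None)
    return toccsl_config(**kw)


def _run_one(cfg: SimConfig, label: str, outdir: Path, preset: ExperimentPreset) -> dict:
    log.info("running %s: %d particles, %d frames", label, cfg.n_particles(), cfg.n_frames())
    record = run_experiment(cfg)
    out: dict = {"label": label, "config": dump_config(cfg)}
    if "density" in preset.analysis:
        series = roi_density(record)
        series.to_dataframe().to_csv(outdir / f"{label}_density.csv", index=False)
        out["density_mean_20_60s"] = (
            series.mean_between(20.0, min(60.0, cfg.duration))
            if cfg.duration > 20
            else float(series.density.mean())
        )
    if "tracking" in preset.analysis or "steps" in preset.analysis:
        trajs = extract_trajectories(record)
        summary = tracking_time_stats(trajs, thresholds=(3.0, 5.0))
        out["tracking"] = summary.to_dict()
        trajectories_dataframe(trajs).to_csv(outdir / f"{label}_trajectories.csv", index=False)
    return out


def run_preset(
    name: str,
    seed: int = 0,
    outdir: str | Path = "photogate_out",
    replicates: int = 1,
    **overrides,
) -> dict:
    """Run a named preset end to end and write its outputs.

    ``replicates`` reruns the experiment with seeds ``seed, seed+1, ...`` to
    emulate multi-cell statistics (one simulation per cell).  Scalar
    ``overrides`` (duration, cell_size, density, ...) are applied on top of
    the preset, which allows reduced-scale runs.  Returns the summary dict
    that is also written to ``summary.json``.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset '{name}'; available: {', '.join(sorted(PRESETS))}")
    preset = PRESETS[name]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"preset": name, "description": preset.description, "seed": seed, "runs": []}

    conditions: list[dict] = [{}] + [dict(c) for c in preset.extra_conditions]
    for cond_i, cond in enumerate(conditions):
        cond_tag = f"cond{cond_i}_" if len(conditions) > 1 else ""
        if preset.sweep_axis is not None:
            base = _build_config(preset, gated=True, seed=seed, extra={**cond, **overrides})
            vals, times, dens = parameter_sweep(base, preset.sweep_axis, preset.sweep_values)
            df = pd.DataFrame(dens.T, columns=[str(v) for v in vals])
            df.insert(0, "time_s", times)
            df.to_csv(outdir / f"{cond_tag}photogate_sweep_{preset.sweep_axis}.csv", index=False)
            at30 = [float(dens[i][np.argmin(np.abs(times - 30.0))]) for i in range(len(vals))]
            results["runs"].append(
                {
                    "label": f"{cond_tag}photogate_sweep",
                    "axis": preset.sweep_axis,
                    "values": list(map(float, vals)),
                    "density_at_30s": at30,
                    "condition": cond,
                }
            )
            if preset.paired_toccsl and preset.sweep_axis != "gate_frequency":
                base_t = _build_config(preset, gated=False, seed=seed, extra={**cond, **overrides})
                vals, times, dens = parameter_sweep(base_t, preset.sweep_axis, preset.sweep_values)
                df = pd.DataFrame(dens.T, columns=[str(v) for v in vals])
                df.insert(0, "time_s", times)
                df.to_csv(outdir / f"{cond_tag}toccsl_sweep_{preset.sweep_axis}.csv", index=False)
                results["runs"].append(
                    {
                        "label": f"{cond_tag}toccsl_sweep",
                        "axis": preset.sweep_axis,
                        "values": list(map(float, vals)),
                        "condition": cond,
                    }
                )
            continue
        for rep in range(replicates):
            rep_tag = f"rep{rep}_" if replicates > 1 else ""
            cfg = _build_config(preset, gated=True, seed=seed + rep, extra={**cond, **overrides})
            results["runs"].append(_run_one(cfg, f"{cond_tag}{rep_tag}photogate", outdir, preset))
            if preset.paired_toccsl:
                cfg = _build_config(preset, gated=False, seed=seed + rep, extra={**cond, **overrides})
                results["runs"].append(_run_one(cfg, f"{cond_tag}{rep_tag}toccsl", outdir, preset))

    with open(outdir / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2)
    log.info("preset %s finished: %d runs -> %s", name, len(results["runs"]), outdir)
    return results
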