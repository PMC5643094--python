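"""End-to-end workflow: synthesis -> analytics -> dwell -> simulation.

A pipeline run is described by a plain dict (usually loaded from YAML):

.. code-block:: yaml

    stages: [synth, analytics, dwell, sim]
    geometry: null          # geometry JSON path; null = built-in ellipse
    tracks: null            # input track CSV when synth is not run
    synth:
      eb1:   {n_comets: 300}
      oskar: {n_particles: 300}
    analytics: {}
    dwell: {}
    sim:
      mode: static          # static | dynamic
      static:  {epsilon: 0.5, T_total: 600.0}
      dynamic: {T_total: 400.0}

All randomness derives from one run seed; each stage gets an independent
child stream, so re-running with the same config and seed reproduces every
number exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np

from . import analytics, dwell as dwell_mod, io, plots
from .geometry import OocyteGeometry, ellipse_geometry, read_geometry, write_geometry
from .sim import (
    DynamicMTConfig,
    StaticRodConfig,
    crescent_score,
    run_cargo_transport,
    run_dynamic_feedback,
    sample_static_rods,
)
from .synthetic import EB1SimParams, OskarSimParams, generate_eb1_tracks, generate_oskar_tracks

log = logging.getLogger("ootrack")

KNOWN_STAGES = ("synth", "analytics", "dwell", "sim")


class PipelineError(RuntimeError):
    pass


def _child_seed(base_seed: int, label: str) -> int:
    ss = np.random.SeedSequence([base_seed, abs(hash(label)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def validate_config(config: dict) -> None:
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}; valid: {KNOWN_STAGES}")
    if not stages:
        raise PipelineError("config names no stages")
    for key in ("geometry", "tracks"):
        path = config.get(key)
        if path is not None and not Path(path).exists():
            raise PipelineError(f"config references absent {key} file: {path}")
    if "synth" not in stages and "tracks" not in config and any(
        s in stages for s in ("analytics", "dwell")
    ):
        raise PipelineError("analytics/dwell stages need either a synth stage or a tracks file")


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Execute the configured stages in order; returns a report dict."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = config["stages"]
    report: dict = {"stages_run": []}

    geom_path = config.get("geometry")
    geom: OocyteGeometry = read_geometry(geom_path) if geom_path else ellipse_geometry()
    write_geometry(geom, out / "geometry.json")

    ts = None
    if config.get("tracks"):
        ts = io.read_tracks(config["tracks"])

    for stage in stages:
        log.info("stage %s", stage)
        try:
            if stage == "synth":
                eb1_kwargs = dict(config.get("synth", {}).get("eb1", {}))
                osk_kwargs = dict(config.get("synth", {}).get("oskar", {}))
                eb1_kwargs.setdefault("seed", _child_seed(seed, "eb1"))
                osk_kwargs.setdefault("seed", _child_seed(seed, "oskar"))
                eb1 = generate_eb1_tracks(EB1SimParams(**eb1_kwargs), geom)
                osk = generate_oskar_tracks(OskarSimParams(**osk_kwargs), geom)
                io.write_tracks(eb1, out / "eb1_tracks.csv")
                io.write_tracks(osk, out / "oskar_tracks.csv")
                ts = eb1
                config["_oskar"] = str(out / "oskar_tracks.csv")
                report["n_eb1_tracks"] = len(eb1)
                report["n_oskar_tracks"] = len(osk)

            elif stage == "analytics":
                if ts is None:
                    raise PipelineError("analytics stage has no tracks")
                osk = io.read_tracks(config["_oskar"]) if config.get("_oskar") else ts
                hist = analytics.direction_histogram(osk, geom)
                io.write_table(hist, out / "direction_histogram.csv")
                freq = analytics.distance_binned_frequency(osk, geom)
                io.write_table(freq, out / "distance_frequency.csv")
                spd = analytics.speed_by_region(ts, geom)
                io.write_table(spd, out / "speed_by_region.csv")
                pct, se, n = analytics.mobile_fraction(osk)
                report["mobile_fraction_pct"] = pct
                io.write_json(
                    {"mobile_fraction_pct": pct, "se_pct": se, "n": n},
                    out / "mobile_fraction.json",
                )
                plots.save(plots.rose_plot(hist), out / "directions_rose.png")
                plots.save(plots.distance_frequency_plot(freq), out / "distance_frequency.png")
                report["speed_by_region"] = spd.to_dict("records")

            elif stage == "dwell":
                if ts is None:
                    raise PipelineError("dwell stage has no tracks")
                events = dwell_mod.select_cortex_tracks(ts, geom, **config.get("dwell", {}))
                edf = dwell_mod.events_frame(events)
                io.write_table(edf, out / "dwell_events.csv")
                post = [e for e in events if e.cortex_region == "posterior"]
                lat = [e for e in events if e.cortex_region == "lateral"]
                if len(post) >= 3 and len(lat) >= 3:
                    comp = dwell_mod.compare_regions(post, lat)
                    fits = comp.pop("fits")
                    comp["fits"] = {
                        k: (dataclasses.asdict(v) if v else None) for k, v in fits.items()
                    }
                    io.write_json(comp, out / "dwell_comparison.json")
                    report["dwell"] = {
                        "mean_posterior": comp["mean_posterior"],
                        "mean_lateral": comp["mean_lateral"],
                        "rank_sum_p": comp["rank_sum_p"],
                    }
                report["n_dwell_events"] = len(events)

            elif stage == "sim":
                sim_cfg = config.get("sim", {})
                mode = sim_cfg.get("mode", "static")
                if mode == "static":
                    cfg = StaticRodConfig(
                        **{**sim_cfg.get("static", {}), "seed": _child_seed(seed, "sim")}
                    )
                    rods = sample_static_rods(cfg, geom)
                    res = run_cargo_transport(rods, cfg, geom)
                    score = crescent_score(res.density, geom)
                    report["crescent_score"] = score
                elif mode == "dynamic":
                    cfg = DynamicMTConfig(
                        **{**sim_cfg.get("dynamic", {}), "seed": _child_seed(seed, "sim")}
                    )
                    res = run_dynamic_feedback(cfg, geom)
                    if res.comet_tracks is not None and len(res.comet_tracks):
                        io.write_tracks(res.comet_tracks, out / "sim_comet_tracks.csv")
                    if res.dwells is not None:
                        io.write_table(res.dwells, out / "sim_dwells.csv")
                else:
                    raise PipelineError(f"unknown sim mode {mode!r}")
                np.savetxt(out / "cargo_density.csv", res.density.counts, delimiter=",")
                plots.save(plots.density_heatmap(res.density, geom), out / "cargo_density.png")
                io.write_json({k: v for k, v in res.meta.items()}, out / "sim_meta.json")
                report["sim_meta"] = res.meta

            report["stages_run"].append(stage)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

    config.pop("_oskar", None)
    io.write_manifest(out, command="run-pipeline", config=config, seed=seed)
    return report
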