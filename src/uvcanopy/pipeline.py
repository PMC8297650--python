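"""End-to-end orchestration: plants -> scene -> trace -> doses -> assays -> fits.

One global seed fans out to per-stage seeds through a fixed
``numpy.random.SeedSequence`` spawning rule, so any stage can be re-run in
isolation and the whole run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import analysis, dosimetry, response, scene as scene_mod, synthetic
from .raytracer import TraceConfig, check_conservation, trace

log = logging.getLogger("uvcanopy.pipeline")

__all__ = ["RunConfig", "run_pipeline", "stage_seeds"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "preset": "14DAT",
    "n_plants": 24,
    "bed_size": [0.8, 0.5],
    "source": {"height": 0.45, "n_bars": 4, "irradiance": {"PAR": 45.0, "UV": 1.0}},
    "trace": {"n_rays": 200_000, "max_bounces": 10, "bands": ["PAR", "UV"]},
    "uv_irradiance_W_m2": 1.0,
    "assay_schedule": "3 d 12 h",
    "assay": {
        "controls": {"tpc_mg_gae_g": 10.0, "tfc_mg_ce_g": 5.0, "rsa_pct": 40.0},
        "yields": {
            "tpc_mg_gae_g": {"form": "F2", "a": 60.0, "b": 20.0},
            "tfc_mg_ce_g": {"form": "F2", "a": 80.0, "b": 25.0},
            "rsa_pct": {"form": "F2", "a": 40.0, "b": 20.0},
        },
        "noise_sd": {"tpc_mg_gae_g": 0.4, "tfc_mg_ce_g": 0.25, "rsa_pct": 1.5},
    },
    "fit_form": "F2",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see DEFAULT_CONFIG for the schema)."""

    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def merged(self) -> dict[str, Any]:
        def deep_merge(base: dict, upd: Mapping) -> dict:
            out = dict(base)
            for k, v in upd.items():
                if isinstance(v, Mapping) and isinstance(out.get(k), dict):
                    out[k] = deep_merge(out[k], v)
                else:
                    out[k] = v
            return out

        cfg = deep_merge(DEFAULT_CONFIG, self.raw)
        if cfg["preset"] not in synthetic.PRESET_CLASS_COUNTS:
            raise ValueError(f"unknown preset {cfg['preset']!r}")
        return cfg


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Fixed fan-out of the global seed into independent per-stage seeds."""
    ss = np.random.SeedSequence(global_seed)
    names = ["plants", "trace_PAR", "trace_UV", "assays"]
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _build_yield_model(spec: Mapping[str, Any]):
    form = spec.get("form", "F2")
    if form == "linear":
        return response.LinearYield(float(spec["slope_pct_per_kJ"]))
    return response.HyperbolicYield(float(spec["a"]), float(spec["b"]), form)


def run_pipeline(config: RunConfig | Mapping[str, Any], out_dir: str | Path) -> Path:
    """Run the whole analysis and write its artifacts under ``out_dir``.

    Produces tally.csv, dose.json, uv_per_leaf.csv, assays.csv, fits.json,
    table1_like.csv and run.log. Rerunning with the same config and seed
    reproduces byte-identical CSV/JSON payloads.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(dict(config))
    cfg = config.merged()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        seeds = stage_seeds(int(cfg["seed"]))
        log.info("stage seeds: %s", seeds)

        # --- plants -------------------------------------------------------
        stage = "plants"
        preset = cfg["preset"]
        counts = synthetic.PRESET_CLASS_COUNTS[preset]
        rng = np.random.default_rng(seeds["plants"])
        plants = []
        for i in range(int(cfg["n_plants"])):
            params = synthetic.preset_params(preset, rng_seed=int(rng.integers(2**31)))
            plant = synthetic.generate_rosette(params, plant_id=i)
            plants.append(synthetic.assign_position_classes(plant, counts))
        log.info("generated %d %s plants", len(plants), preset)

        # --- scene --------------------------------------------------------
        stage = "scene"
        bed = tuple(cfg["bed_size"])
        src = cfg["source"]
        sources = scene_mod.default_bar_sources(
            bed, height=src["height"], n_bars=src["n_bars"],
            irradiance_W_m2=src["irradiance"],
        )
        scn = scene_mod.build_scene(plants, None, bed, sources)
        lai = analysis.leaf_area_index(scn.plants, scn.bed_area)
        log.info("scene: %d plants, LAI %.3f", len(scn.plants), lai)

        # --- trace per band -----------------------------------------------
        stage = "trace"
        tallies = []
        results = {}
        for band in cfg["trace"]["bands"]:
            tc = TraceConfig(
                n_rays=int(cfg["trace"]["n_rays"]),
                max_bounces=int(cfg["trace"]["max_bounces"]),
                rng_seed=seeds.get(f"trace_{band}", seeds["trace_UV"]),
                band=band,
            )
            res = trace(scn, tc)
            report = check_conservation(res)
            if not report["ok"]:
                raise RuntimeError(f"energy balance violated in band {band}: {report}")
            results[band] = res
            t = res.surfaces.copy()
            t["band"] = band
            tallies.append(t)
            log.info(
                "traced %s: emitted %.3f W, absorbed %.3f W, escaped %.3f W",
                band, res.emitted_W, res.absorbed_total_W, res.escaped_W,
            )
        tally = pd.concat(tallies, ignore_index=True)
        tally.to_csv(out / "tally.csv", index=False)

        # --- dosimetry ----------------------------------------------------
        stage = "dose"
        uv_e = float(cfg["uv_irradiance_W_m2"])
        lamp = dosimetry.gaussian_led_spectrum(310.0, 10.0, uv_e)
        be = dosimetry.be_factor(lamp)
        doses = [
            {
                "label": s.label,
                "hours_per_day": s.hours_per_day,
                "n_days": s.n_days,
                "unweighted_kJ_m2": dosimetry.cumulative_dose(uv_e, s),
                "be_factor": be,
                "be_kJ_m2": be * dosimetry.cumulative_dose(uv_e, s),
            }
            for s in dosimetry.treatment_grid()
        ]
        (out / "dose.json").write_text(json.dumps(doses, indent=2))

        # --- per-leaf cumulative UV over the six treatments ----------------
        stage = "cumulative_uv"
        uv_result = results.get("UV")
        if uv_result is None:
            raise RuntimeError("a UV-band trace is required for dose integration")
        grids = dosimetry.treatment_grid()
        duv_frames = []
        for s in grids:
            duv = analysis.cumulative_absorbed_uv(uv_result, s)
            duv["treatment"] = s.label
            duv_frames.append(duv)
        assay_sched = cfg["assay_schedule"]
        per_leaf = next(
            f for f, s in zip(duv_frames, grids) if s.label == assay_sched
        )
        per_leaf.drop(columns="treatment").to_csv(out / "uv_per_leaf.csv", index=False)

        # --- synthetic assays ----------------------------------------------
        stage = "assays"
        control = duv_frames[0].copy()
        control["treatment"] = "control"
        control["cumulative_absorbed_uv_kJ_m2"] = 0.0
        duv_all = pd.concat(duv_frames + [control], ignore_index=True)
        models = {k: _build_yield_model(v) for k, v in cfg["assay"]["yields"].items()}
        assays = synthetic.generate_assay_data(
            duv_all,
            yield_models=models,
            control_concentration=cfg["assay"]["controls"],
            noise_sd=cfg["assay"]["noise_sd"],
            rng_seed=seeds["assays"],
        )
        assays.to_csv(out / "assays.csv", index=False)

        # --- yield fits -----------------------------------------------------
        stage = "fits"
        linear, nonlinear = response.fit_yields_by_group(
            assays,
            compound_columns=("tfc_mg_ce_g", "tpc_mg_gae_g"),
            stage=preset,
            form=cfg["fit_form"],
        )
        fits_doc = {
            "linear": [vars(f) for f in linear],
            "nonlinear": [vars(f) for f in nonlinear],
            "seed": cfg["seed"],
        }
        (out / "fits.json").write_text(json.dumps(fits_doc, indent=2))
        response.yield_report(linear, nonlinear).to_csv(
            out / "table1_like.csv", index=False
        )
        log.info("pipeline complete in %.1f s", time.time() - t0)
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
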