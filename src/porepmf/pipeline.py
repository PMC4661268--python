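"""End-to-end pipeline: plan -> sample -> WHAM -> project -> states -> hydration.

A single structured config (YAML or JSON) drives the whole run; every stage
artifact is written under the output directory and recorded in a manifest
(config hash, master seed, per-stage status, file list), so a run is
reproducible byte-for-byte from its config.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import porepmf
from porepmf.synthetic.surfaces import ModelSurfaceSpec
from porepmf.synthetic.sampler import SamplerConfig
from porepmf.synthetic.occupancy import (
    OccupancySeriesSpec,
    generate_occupancy_series,
    write_occupancy_csv,
)
from porepmf import umbrella, wham, hydration

logger = logging.getLogger("porepmf")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and partial outputs."""

    def __init__(self, stage: str, message: str, partial_outputs: list[str]):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.partial_outputs = partial_outputs


@dataclass
class RunConfig:
    """Validated pipeline configuration with paper-shaped defaults.

    A bare config (flat defaults) runs the default experiment: a 0.5 A
    diagonal window plan with k = 3 kcal/mol/A^2 on the (8.0, 13.5) A domain
    at 300 K, WHAM at 0.1 A bins, opening free energy read at 11.5 A.
    """

    surface: dict = field(default_factory=lambda: {"kind": "flat"})
    domain: tuple[float, float] = (8.0, 13.5)
    plan: dict = field(
        default_factory=lambda: {"mode": "diagonal", "spacing": 0.5, "k": 3.0}
    )
    sampler: dict = field(
        default_factory=lambda: {
            "n_steps": 20000,
            "temperature": 300.0,
            "step_size": 0.15,
            "seed": 0,
        }
    )
    wham: dict = field(
        default_factory=lambda: {
            "bin_width": 0.1,
            "tolerance": 1e-4,
            "max_iter": 1000,
            "symmetrize": False,
        }
    )
    states: dict = field(default_factory=lambda: {"open_zeta": 11.5})
    hydration: dict | None = None
    out_dir: str = "run_output"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.domain = tuple(cfg.domain)
        # validate eagerly so errors carry the offending stage name
        cfg.surface_spec()
        cfg.sampler_config()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def surface_spec(self) -> ModelSurfaceSpec:
        s = dict(self.surface)
        kind = s.pop("kind")
        if kind == "flat":
            return ModelSurfaceSpec.flat(self.domain)
        if kind == "opening_profile":
            return ModelSurfaceSpec.opening_profile(domain=self.domain, **s)
        return ModelSurfaceSpec(kind, s, self.domain)

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(**self.sampler)

    def canonical_json(self) -> str:
        def default(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return json.dumps(d, sort_keys=True, default=default)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _write_pmf_csv(surface: wham.PMFSurface, path: Path) -> None:
    g1, g2 = np.meshgrid(surface.centers1, surface.centers2, indexing="ij")
    pd.DataFrame(
        {
            "zeta1": g1.ravel(),
            "zeta2": g2.ravel(),
            "F_kcal_mol": surface.values.ravel(),
            "sampled": surface.sampled.ravel().astype(int),
        }
    ).to_csv(path, index=False, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and write) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stages: dict[str, str] = {}
    t0 = time.time()

    def record(path: Path) -> None:
        outputs.append(str(path.relative_to(out_dir)))

    def run_stage(name: str, fn):
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            stages[name] = f"error: {exc}"
            raise PipelineError(name, str(exc), outputs) from exc
        stages[name] = "ok"
        logger.info("stage %s: ok", name)
        return result

    # plan
    def do_plan():
        plan = umbrella.plan_windows(
            domain=config.domain,
            spacing=config.plan.get("spacing", 0.5),
            mode=config.plan.get("mode", "diagonal"),
            k=config.plan.get("k", 3.0),
        )
        plan.to_json(out_dir / "plan.json")
        record(out_dir / "plan.json")
        return plan

    plan = run_stage("plan", do_plan)

    # sample
    def do_sample():
        spec = config.surface_spec()
        cfg = config.sampler_config()
        windows = umbrella.run_umbrella_set(plan, spec, cfg)
        for w in windows:
            logger.info(
                "window %s acceptance %.3f", w.id, w.trajectory.acceptance_rate
            )
        manifest_path = umbrella.write_manifest(
            windows, out_dir / "trajectories", cfg.temperature
        )
        record(manifest_path)
        for w in windows:
            record(out_dir / "trajectories" / f"{w.id}.csv")
        return windows

    windows = run_stage("sample", do_sample)

    # wham
    def do_wham():
        stripped = [umbrella.strip_burn_in(w) for w in windows]
        hists = wham.histogram_windows(
            stripped, config.wham.get("bin_width", 0.1), config.domain
        )
        surface, report = wham.wham_solve(
            hists,
            [w.bias for w in windows],
            temperature=config.sampler.get("temperature", 300.0),
            tolerance=config.wham.get("tolerance", 1e-4),
            max_iter=config.wham.get("max_iter", 1000),
        )
        if config.wham.get("symmetrize", False):
            surface = wham.symmetrize(surface)
        _write_pmf_csv(surface, out_dir / "pmf2d.csv")
        record(out_dir / "pmf2d.csv")
        conv = {
            "iterations": report.iterations,
            "tolerance": report.tolerance,
            "converged": report.converged,
            "max_delta_f": report.max_delta_f,
        }
        (out_dir / "convergence.json").write_text(json.dumps(conv, indent=2))
        record(out_dir / "convergence.json")
        return surface, report

    surface, report = run_stage("wham", do_wham)

    # project
    def do_project():
        profile = wham.project_diagonal(surface)
        pd.DataFrame({"zeta": profile.zeta, "F_kcal_mol": profile.values}).to_csv(
            out_dir / "profile1d.csv", index=False, float_format="%.6f"
        )
        record(out_dir / "profile1d.csv")
        return profile

    profile = run_stage("project", do_project)

    # states
    def do_states():
        summary = wham.locate_states(
            profile, open_zeta=config.states.get("open_zeta", 11.5)
        )
        payload = {
            "minimum_zeta_A": summary.minimum[0],
            "minimum_F_kcal_mol": summary.minimum[1],
            "barrier_zeta_A": summary.barrier[0] if summary.barrier else None,
            "barrier_height_kcal_mol": summary.barrier_height,
            "delta_g_open_kcal_mol": summary.delta_g_open,
            "open_zeta_A": summary.open_zeta,
        }
        (out_dir / "states.json").write_text(json.dumps(payload, indent=2))
        record(out_dir / "states.json")
        return summary

    run_stage("states", do_states)

    # hydration (optional)
    if config.hydration is not None:
        def do_hydration():
            h = dict(config.hydration)
            n_frames = h.pop("n_frames", 500)
            geometry = hydration.PoreGeometry(
                reference_radius=h.pop("reference_radius", 5.0),
                z_range=tuple(h.pop("z_range", (-15.0, 5.0))),
            )
            bulk = h.pop("bulk", hydration.BULK_DENSITY)
            thr = h.pop("threshold_fraction", 0.5)
            spec = OccupancySeriesSpec(
                z_range=geometry.z_range,
                seed=config.sampler.get("seed", 0),
                **h,
            )
            frames = generate_occupancy_series(spec, n_frames)
            write_occupancy_csv(frames, out_dir / "occupancy.csv")
            record(out_dir / "occupancy.csv")
            prof = hydration.density_profile(frames, geometry)
            prof.to_csv(out_dir / "density_profile.csv")
            record(out_dir / "density_profile.csv")
            intervals = hydration.classify_wetting(prof, bulk, thr)
            hydration.write_wetting_json(intervals, out_dir / "wetting.json")
            record(out_dir / "wetting.json")

        run_stage("hydration", do_hydration)

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash,
        "seed": config.sampler.get("seed", 0),
        "version": porepmf.__version__,
        "stages": stages,
        "outputs": sorted(outputs),
        "wham_iterations": report.iterations,
        "elapsed_s": round(time.time() - t0, 3),
        "out_dir": str(out_dir),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def compare_runs(manifest_a: dict | str | Path, manifest_b: dict | str | Path) -> dict:
    """Aligned summary of the state analysis of two runs, with differences.

    Raises a ``ValueError`` for manifests produced on incompatible domains.
    """
    def load(m):
        if isinstance(m, (str, Path)):
            m = json.loads(Path(m).read_text())
        states = json.loads((Path(m["out_dir"]) / "states.json").read_text())
        return m, states

    ma, sa = load(manifest_a)
    mb, sb = load(manifest_b)
    if list(ma["config"]["domain"]) != list(mb["config"]["domain"]):
        raise ValueError("runs use incompatible reaction-coordinate domains")

    keys = ("minimum_zeta_A", "barrier_height_kcal_mol", "delta_g_open_kcal_mol")
    table = {}
    for key in keys:
        a, b = sa[key], sb[key]
        diff = None if (a is None or b is None) else a - b
        table[key] = {"a": a, "b": b, "difference": diff}
    return table
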