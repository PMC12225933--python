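"""Reproducible pipeline runs: config, seeds, manifests, stage glue.

A run is described by a flat key=value config whose mechanical keys carry
the same symbols as the species parameter table (``E_epid``, ``nu_dermis``,
``gT_epid``, ...), so a config can be diffed against the table directly.
Every stage derives its own seed from the global seed by a fixed rule
(``numpy.random.SeedSequence(global_seed, spawn_key=(stage_index,))``,
reduced mod 2**31), and a manifest records the config hash, derived seeds,
stage outputs and their SHA-256 digests — re-running the same config must
reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, config as defaults
from . import io as dio
from . import mechanics as mech
from . import pattern as pat
from . import segmentation as seg
from . import synthetic as syn
from . import indentation as ind

logger = logging.getLogger(__name__)

STAGES = (
    "generate-mesh", "generate-phantom", "generate-curves",
    "simulate", "analyze-pattern", "segment", "fit-indentation",
)


@dataclass
class RunConfig:
    """Flat configuration of a pipeline run."""

    stages: list = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    out: str = "run"
    log_level: str = "INFO"
    species: str = "sulcata"

    # mechanical parameters (overridden by `species` unless use_species=0)
    use_species: int = 1
    E_epid: float = 3.0
    E_dermis: float = 1.0
    nu_epid: float = 0.1
    nu_dermis: float = 0.4
    gT_epid: float = 0.6
    gN_epid: float = 0.0
    gT_dermis: float = 0.6
    gN_dermis: float = 0.3
    ramp_steps: int = defaults.RAMP_STEPS
    growth_noise: float = defaults.GROWTH_NOISE_AMPLITUDE

    # cap geometry
    cap_radius: float = defaults.CAP_RADIUS
    h_epid: float = defaults.CAP_H_EPIDERMIS
    h_dermis: float = defaults.CAP_H_DERMIS
    resolution: int = defaults.CAP_RESOLUTION
    perturb_amplitude: float = defaults.PERTURB_AMPLITUDE
    half_width_fraction: float = defaults.CAP_HALF_WIDTH_FRACTION

    # solver
    tol: float = defaults.RESIDUAL_TOL
    max_steps_per_increment: int = defaults.MAX_STEPS_PER_INCREMENT
    final_relax_steps: int = defaults.FINAL_RELAX_STEPS

    # phantom
    phantom_shape: tuple = (64, 96, 96)
    phantom_h_epid: float = 8.0
    phantom_h_dermis: float = 20.0
    n_cells: int = 20
    noise_sd: float = 0.0

    # indentation
    E_true: float = 1e5
    probe_radius: float = defaults.PROBE_RADIUS_UM
    max_depth: float = defaults.MAX_DEPTH_UM
    n_curves: int = 30
    curve_noise_sd: float = 0.01
    grid_rows: int = 3
    grid_cols: int = 10

    def material_growth(self):
        if self.use_species:
            return mech.species_parameters(self.species)
        mat = mech.MaterialSpec(self.E_epid, self.E_dermis,
                                self.nu_epid, self.nu_dermis)
        gro = mech.GrowthSpec(self.gT_epid, self.gN_epid,
                              self.gT_dermis, self.gN_dermis,
                              ramp_steps=self.ramp_steps,
                              noise_amplitude=self.growth_noise)
        return mat, gro


_INT_LIKE = {"seed", "use_species", "ramp_steps", "resolution",
             "max_steps_per_increment", "final_relax_steps", "n_cells",
             "n_curves", "grid_rows", "grid_cols"}


def config_to_text(cfg: RunConfig) -> str:
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, (list, tuple)):
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> RunConfig:
    known = {f.name: f for f in fields(RunConfig)}
    kwargs = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value': {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ValueError(f"unknown config key {key!r} (line {lineno})")
        if key == "stages":
            kwargs[key] = [s.strip() for s in val.split(",") if s.strip()]
        elif key == "phantom_shape":
            kwargs[key] = tuple(int(x) for x in val.split(","))
        elif key in _INT_LIKE:
            kwargs[key] = int(val)
        elif key in ("out", "log_level", "species"):
            kwargs[key] = val
        else:
            kwargs[key] = float(val)
    cfg = RunConfig(**kwargs)
    for s in cfg.stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {', '.join(STAGES)}")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derivation (documented contract)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(int(global_seed), spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the manifest.

    Stage order is fixed; a stage failure is recorded and the dependent
    downstream stages are skipped.  The manifest contains no timestamps, so
    identical configs yield identical manifests.
    """
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))

    cfg_text = config_to_text(cfg)
    (out / "config.txt").write_text(cfg_text)
    # hash the config without the output location, so identical runs into
    # different directories produce identical manifests
    hashed = "\n".join(l for l in cfg_text.splitlines()
                       if not l.startswith("out ="))
    manifest: dict = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(hashed.encode()).hexdigest(),
        "global_seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in cfg.stages},
        "stages": {},
    }

    state: dict = {}
    failed = False
    for stage in [s for s in STAGES if s in cfg.stages]:
        entry: dict = {"inputs": [], "outputs": []}
        if failed:
            entry["status"] = "skipped"
            manifest["stages"][stage] = entry
            continue
        try:
            outputs = _run_stage(stage, cfg, state, out,
                                 stage_seed(cfg.seed, stage), entry)
            entry["status"] = "ok"
            entry["outputs"] = [
                {"file": str(p.relative_to(out)), "sha256": _sha256(p)}
                for p in outputs
            ]
        except Exception as exc:       # noqa: BLE001 — recorded, not hidden
            logger.exception("stage %s failed", stage)
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            failed = True
        manifest["stages"][stage] = entry

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def _run_stage(stage, cfg: RunConfig, state, out: Path, seed: int,
               entry: dict) -> list[Path]:
    mat, gro = cfg.material_growth()
    if stage == "generate-mesh":
        mesh = syn.make_layered_cap(
            cap_radius=cfg.cap_radius, h_epid=cfg.h_epid,
            h_dermis=cfg.h_dermis, resolution=cfg.resolution,
            perturb_amplitude=cfg.perturb_amplitude, seed=seed,
            half_width_fraction=cfg.half_width_fraction,
        )
        state["mesh"] = mesh
        return [dio.write_vtk_mesh(out / "mesh.vtk", mesh)]

    if stage == "generate-phantom":
        ph = syn.make_image_phantom(
            shape=tuple(cfg.phantom_shape), h_epid=cfg.phantom_h_epid,
            h_dermis=cfg.phantom_h_dermis, n_cells=cfg.n_cells,
            noise_sd=cfg.noise_sd, seed=seed,
        )
        state["phantom"] = ph
        p = dio.write_phantom(out / "phantom.tif", ph)
        return [p, p.with_suffix(".json"), p.with_suffix(".bone.npy")]

    if stage == "generate-curves":
        curves = syn.make_indentation_curves(
            E_true=cfg.E_true, probe_radius=cfg.probe_radius,
            max_depth=cfg.max_depth, n_curves=cfg.n_curves,
            noise_sd=cfg.curve_noise_sd, seed=seed,
        )
        state["curves"] = curves
        d = dio.write_curves(out / "curves", curves)
        entry["n_curves"] = len(curves)
        return sorted(d.glob("*"))

    if stage == "simulate":
        mesh = state["mesh"]
        entry["inputs"] = ["mesh.vtk"]
        opts = mech.SimOptions(
            tol=cfg.tol, max_steps_per_increment=cfg.max_steps_per_increment,
            final_relax_steps=cfg.final_relax_steps, seed=seed,
        )
        st, snaps, diag = mech.simulate(mesh, mat, gro, opts)
        state["sim_state"] = st
        outputs = [dio.write_vtk_mesh(out / "deformed.vtk", mesh,
                                      positions=st.positions)]
        for i, (frac, pos) in enumerate(snaps):
            outputs.append(dio.write_vtk_mesh(
                out / f"snapshot_{i:03d}.vtk", mesh, positions=pos))
        diag.to_csv(out / "diagnostics.csv", index=False)
        outputs.append(out / "diagnostics.csv")
        entry["converged_final"] = bool(diag["converged"].iloc[-1])
        return outputs

    if stage == "analyze-pattern":
        st = state["sim_state"]
        entry["inputs"] = ["deformed.vtk"]
        surf = mech.free_surface(st.mesh, st.positions)
        pat.surface_curvature(surf)
        net = pat.extract_creases(
            surf, threshold=defaults.CREASE_FIXED_THRESHOLD)
        dom = pat.segment_domains(surf, net)
        stats = pat.pattern_statistics(surf, net, dom)
        outputs = [dio.write_surface_ply(out / "surface.ply", surf)]
        outputs.append(out / "surface.ply.scalars.json")
        pd.DataFrame(net.crease_edges,
                     columns=["v0", "v1"]).to_csv(out / "crease_edges.csv",
                                                  index=False)
        outputs.append(out / "crease_edges.csv")
        (out / "pattern_stats.json").write_text(json.dumps(
            {k: (None if v is None else float(v) if np.isscalar(v) else v)
             for k, v in vars(stats).items()}, indent=2, sort_keys=True))
        outputs.append(out / "pattern_stats.json")
        state["pattern_stats"] = stats
        return outputs

    if stage == "segment":
        ph = state["phantom"]
        entry["inputs"] = ["phantom.tif"]
        edges = seg.canny_edges_3d(ph.stack)
        clouds = seg.split_edge_surfaces(ph.stack, edges)
        outer = seg.reconstruct_surface(clouds["outer"])
        inner = seg.reconstruct_surface(clouds["inner"])
        th = seg.thickness_map(outer, inner)
        cells = seg.detect_cells(ph.stack)
        dens = seg.proliferation_density(cells, ph.layer_masks())
        outputs = [
            dio.write_surface_ply(out / "epidermis_outer.ply", outer),
            out / "epidermis_outer.ply.scalars.json",
            dio.write_surface_ply(out / "epidermis_inner.ply", inner),
        ]
        pd.DataFrame(cells.centroids,
                     columns=["z", "y", "x"]).assign(
            score=cells.scores).to_csv(out / "cells.csv", index=False)
        outputs.append(out / "cells.csv")
        dens.to_csv(out / "layer_densities.csv", index=False)
        outputs.append(out / "layer_densities.csv")
        entry["thickness_mean"] = float(np.nanmean(th))
        entry["n_cells_detected"] = int(len(cells))
        return outputs

    if stage == "fit-indentation":
        curves = state["curves"]
        entry["inputs"] = ["curves/"]
        results = [ind.fit_hertz(c) for c in curves]
        rows = [{
            "curve_id": r.curve_id, "replicate_id": r.replicate_id,
            "E_eff": r.E_eff, "fit_quality": r.fit_quality,
        } for r in results]
        pd.DataFrame(rows).to_csv(out / "indentation_results.csv",
                                  index=False)
        summary = ind.filter_and_aggregate(results)
        summary.to_csv(out / "indentation_summary.csv", index=False)
        return [out / "indentation_results.csv",
                out / "indentation_summary.csv"]

    raise ValueError(f"unknown stage {stage!r}")


def compare_species_runs(
    species=("sulcata", "graeca", "marginata"),
    seeds=(11, 12, 13),
    sim_options: mech.SimOptions | None = None,
    cap_kwargs: dict | None = None,
) -> dict:
    """Run the full cross-species protocol and rank the fold patterns.

    For each species and seed, generate the default layered cap, simulate
    the tabulated growth, extract the crease network at the fixed
    comparison threshold, and feed the statistics to
    :func:`dermafold.pattern.compare_species`.
    """
    cap_kwargs = cap_kwargs or {}
    all_stats: dict[str, list[pat.PatternStats]] = {}
    for sp in species:
        mat, gro = mech.species_parameters(sp)
        entries = []
        for seed in seeds:
            mesh = syn.make_layered_cap(seed=seed, **cap_kwargs)
            opts = sim_options or mech.SimOptions()
            opts = mech.SimOptions(**{**vars(opts), "seed": seed})
            st, _, _ = mech.simulate(mesh, mat, gro, opts)
            surf = mech.free_surface(mesh, st.positions)
            pat.surface_curvature(surf)
            net = pat.extract_creases(
                surf, threshold=defaults.CREASE_FIXED_THRESHOLD)
            dom = pat.segment_domains(surf, net)
            entries.append(pat.pattern_statistics(surf, net, dom))
            logger.info("%s seed %d: crease density %.4f", sp, seed,
                        entries[-1].crease_length_density)
        all_stats[sp] = entries
    report = pat.compare_species(all_stats)
    return report
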