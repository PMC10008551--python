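"""End-to-end orchestration: simulate → qc → convert → cluster → diet → isoscape → assign.

A single nested config (YAML/JSON-compatible mapping) drives the run;
every stage writes CSV/JSON artefacts into the run directory and the
whole run is recorded in a manifest holding the config hash, seeds and
SHA-256 digests of all inputs and outputs.  Deterministic stages are
skipped on re-run when their input digests are unchanged and their
outputs still exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from . import isoscape as iso
from . import mixing as mx
from . import synth
from .oxygen import DEFAULT_WATER_SIGMA, convert_array
from .samples import QCConfig, apply_qc, load_samples, samples_to_frame

log = logging.getLogger("isomix")

__all__ = ["RunManifest", "validate_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {"enabled": True, "n_isoscape_points": 200},
    "input": {},
    "qc": {"cn_min": 2.9, "cn_max": 3.6, "min_yield": 1.0},
    "convert": {"sigma": DEFAULT_WATER_SIGMA},
    "cluster": {
        "diet": {"columns": ["d13C_coll", "d15N"], "k_max": 5, "restarts": 10},
        "oxygen": {"k": 2, "trim": 0.05, "restarts": 10},
    },
    "diet": {
        "enabled": True,
        "use_default_sources": True,
        "mcmc": {"chains": 4, "iterations": 4000, "burn_in": 2000, "thinning": 1},
    },
    "isoscape": {
        "grid": {"lon_min": -10.0, "lon_max": 30.0, "lat_min": 35.0, "lat_max": 60.0, "cell": 0.5}
    },
    "assign": {"sigma_individual": DEFAULT_WATER_SIGMA},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    """Merge over defaults and check schema; raises listing bad fields."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    problems = []
    if not isinstance(cfg.get("seed"), int):
        problems.append("seed: integer required")
    if not cfg["simulate"].get("enabled") and not cfg["input"].get("samples"):
        problems.append("input.samples: required when simulate.enabled is false")
    diet = cfg["diet"]
    if diet.get("enabled") and not (diet.get("use_default_sources") or diet.get("problem")):
        problems.append("diet.problem (sources block) or diet.use_default_sources: required when diet.enabled")
    trim = cfg["cluster"]["oxygen"].get("trim", 0.05)
    if not (0 <= trim < 0.5):
        problems.append("cluster.oxygen.trim: must be in [0, 0.5)")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, name: str, inputs: list[Path], outputs: list[Path], status: str, elapsed: float) -> None:
        self.stages[name] = {
            "status": status,
            "elapsed_s": round(elapsed, 3),
            "inputs": {p.name: _digest(p) for p in inputs if p.exists()},
            "outputs": {p.name: _digest(p) for p in outputs if p.exists()},
        }

    def save(self, path: Path) -> None:
        self.finished = time.time()
        path.write_text(json.dumps(asdict(self), indent=2))


def _load_previous(outdir: Path) -> dict:
    p = outdir / "manifest.json"
    if p.exists():
        try:
            return json.loads(p.read_text()).get("stages", {})
        except json.JSONDecodeError:
            return {}
    return {}


def _cached(prev: dict, name: str, inputs: list[Path], outputs: list[Path]) -> bool:
    st = prev.get(name)
    if not st or st.get("status") not in {"ok", "cached"}:
        return False
    if any(not p.exists() for p in outputs):
        return False
    want = st.get("inputs", {})
    have = {p.name: _digest(p) for p in inputs if p.exists()}
    if set(want) != set(have) or any(want[k] != have[k] for k in want):
        return False
    saved = st.get("outputs", {})
    return all(_digest(p) == saved.get(p.name) for p in outputs)


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute all enabled stages in dependency order; returns the manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    cfg_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(config_hash=cfg_hash, seed=seed)
    prev = _load_previous(outdir)

    def stage(name, inputs, outputs, fn):
        t0 = time.time()
        if _cached(prev, name, inputs, outputs):
            log.info("stage %s: cached", name)
            manifest.record(name, inputs, outputs, "cached", time.time() - t0)
            return
        try:
            fn()
        except Exception:
            manifest.record(name, inputs, outputs, "failed", time.time() - t0)
            manifest.save(outdir / "manifest.json")
            raise
        manifest.record(name, inputs, outputs, "ok", time.time() - t0)
        log.info("stage %s: ok (%.2fs)", name, time.time() - t0)

    # -- simulate ----------------------------------------------------------
    if cfg["simulate"].get("enabled"):
        samples_csv = outdir / "samples.csv"
        iso_csv = outdir / "isoscape_points.csv"

        def _simulate():
            spec = synth.PopulationSpec(seed=seed)
            synth.simulate_all(spec, outdir, n_isoscape_points=cfg["simulate"]["n_isoscape_points"])

        stage("simulate", [], [samples_csv, iso_csv], _simulate)
    else:
        samples_csv = Path(cfg["input"]["samples"])
        iso_csv = Path(cfg["input"].get("isoscape_points", "")) if cfg["input"].get("isoscape_points") else None

    # -- qc ----------------------------------------------------------------
    accepted_csv = outdir / "accepted.csv"
    qc_json = outdir / "qc_report.json"

    def _qc():
        samples = load_samples(samples_csv)
        qc_conf = QCConfig(**{k: cfg["qc"][k] for k in ("cn_min", "cn_max", "min_yield")})
        accepted, report = apply_qc(samples, qc_conf)
        df = samples_to_frame(samples)
        df["collagen_ok"] = [report.per_sample[s].collagen_ok for s in df["sample_id"]]
        df["carbonate_ok"] = [report.per_sample[s].carbonate_ok for s in df["sample_id"]]
        df[df["collagen_ok"]].to_csv(accepted_csv, index=False)
        qc_json.write_text(report.to_json())

    stage("qc", [samples_csv], [accepted_csv, qc_json], _qc)

    # -- convert -----------------------------------------------------------
    converted_csv = outdir / "converted.csv"

    def _convert():
        df = pd.read_csv(accepted_csv)
        ok = df["carbonate_ok"].astype(bool) & df["d18O_carb_vpdb"].notna()
        water = np.full(len(df), np.nan)
        water[ok.to_numpy()] = convert_array(df.loc[ok, "d18O_carb_vpdb"].to_numpy())
        df["d18O_water_vsmow"] = water
        df["d18O_water_sigma"] = np.where(np.isfinite(water), cfg["convert"]["sigma"], np.nan)
        df.to_csv(converted_csv, index=False)

    stage("convert", [accepted_csv], [converted_csv], _convert)

    # -- cluster -----------------------------------------------------------
    diet_clusters_csv = outdir / "diet_clusters.csv"
    diet_model_json = outdir / "diet_cluster_model.json"
    oxy_clusters_csv = outdir / "oxygen_clusters.csv"
    oxy_model_json = outdir / "oxygen_cluster_model.json"

    def _cluster():
        df = pd.read_csv(converted_csv)
        ccfg = cfg["cluster"]["diet"]
        sub = df[
            (df["species"] == "human")
            & (df["age_class"] == "adult")
            & df[ccfg["columns"]].notna().all(axis=1)
        ]
        sol = cl.fit_gmm_bic(
            sub[ccfg["columns"]].to_numpy(),
            k_range=range(1, ccfg["k_max"] + 1),
            restarts=ccfg["restarts"],
            seed=seed,
        )
        out = sub[["sample_id"]].copy()
        out["diet_cluster"] = sol.assignments
        out.to_csv(diet_clusters_csv, index=False)
        diet_model_json.write_text(
            json.dumps(
                {
                    "k": sol.k,
                    "family": sol.covariance_family,
                    "bic": sol.bic,
                    "weights": sol.weights.tolist(),
                    "means": sol.means.tolist(),
                    "sizes": sol.cluster_sizes(),
                },
                indent=2,
                default=str,
            )
        )

        ocfg = cfg["cluster"]["oxygen"]
        osub = df[(df["species"] == "human") & df["d18O_water_vsmow"].notna()]
        osol = cl.fit_trimmed_1d(
            osub["d18O_water_vsmow"].to_numpy(),
            k=ocfg["k"],
            trim_fraction=ocfg["trim"],
            restarts=ocfg["restarts"],
            seed=seed,
        )
        oout = osub[["sample_id", "d18O_water_vsmow"]].copy()
        oout["oxygen_cluster"] = osol.assignments
        oout.to_csv(oxy_clusters_csv, index=False)
        oxy_model_json.write_text(
            json.dumps(
                {
                    "k": osol.k,
                    "family": osol.covariance_family,
                    "means": osol.means.tolist(),
                    "variances": np.asarray(osol.covariances).tolist(),
                    "n_outliers": osol.n_outliers,
                    "sizes": osol.cluster_sizes(),
                },
                indent=2,
                default=str,
            )
        )

    stage("cluster", [converted_csv], [diet_clusters_csv, diet_model_json, oxy_clusters_csv, oxy_model_json], _cluster)

    # -- diet mixing -------------------------------------------------------
    diet_outputs = [outdir / "diet_summary.json", outdir / "diet_draws.csv", outdir / "diet_diagnostics.json"]
    if cfg["diet"].get("enabled"):

        def _diet():
            df = pd.read_csv(converted_csv).merge(pd.read_csv(diet_clusters_csv), on="sample_id")
            mcfg = cfg["diet"]["mcmc"]
            summaries, diags, draw_frames = {}, {}, []
            for cluster_id, grp in df.groupby("diet_cluster"):
                if cluster_id == cl.OUTLIER or len(grp) < 3:
                    continue
                proxies = []
                for p in ("d13C_coll", "d15N", "d13C_carb"):
                    vals = grp[p].dropna()
                    if len(vals) >= 3:
                        proxies.append(mx.ProxyTarget(p, float(vals.mean()), max(float(vals.std(ddof=1)), 0.1)))
                if cfg["diet"].get("problem"):
                    base = mx.problem_from_config(cfg["diet"]["problem"])
                    problem = mx.build_problem(base.sources, proxies, base.offsets, base.routing, base.constraints)
                else:
                    problem = mx.build_problem(
                        mx.default_sources(), proxies, mx.default_offsets(), mx.default_routing()
                    )
                post = mx.sample_posterior(
                    problem,
                    mx.McmcSettings(
                        seed=seed + int(cluster_id),
                        chains=mcfg["chains"],
                        iterations=mcfg["iterations"],
                        burn_in=mcfg["burn_in"],
                        thinning=mcfg.get("thinning", 1),
                    ),
                )
                summaries[str(cluster_id)] = mx.summarize_posterior(post, problem).reset_index().to_dict("records")
                diags[str(cluster_id)] = {
                    "rhat": post.rhat.tolist(),
                    "ess": post.ess.tolist(),
                    "accept_rate": post.accept_rate,
                    "converged": post.converged,
                }
                dd = pd.DataFrame(post.draws, columns=post.source_names)
                dd.insert(0, "diet_cluster", cluster_id)
                draw_frames.append(dd)
            diet_outputs[0].write_text(json.dumps(summaries, indent=2, default=float))
            pd.concat(draw_frames, ignore_index=True).to_csv(diet_outputs[1], index=False)
            diet_outputs[2].write_text(json.dumps(diags, indent=2, default=float))

        stage("diet", [converted_csv, diet_clusters_csv], diet_outputs, _diet)

    # -- isoscape ----------------------------------------------------------
    grid_csv = outdir / "isoscape_grid.csv"
    iso_meta_json = outdir / "isoscape_meta.json"
    if iso_csv is not None:

        def _isoscape():
            points = iso.load_isoscape_points(iso_csv)
            gs = iso.GridSpec(**cfg["isoscape"]["grid"])
            surface = iso.fit_isoscape(points, gs, seed=seed)
            surface.to_frame().to_csv(grid_csv, index=False)
            iso_meta_json.write_text(json.dumps(surface.meta, indent=2, default=str))

        stage("isoscape", [iso_csv], [grid_csv, iso_meta_json], _isoscape)

        # -- assign --------------------------------------------------------
        assign_json = outdir / "residence_summary.json"
        assign_csv = outdir / "residence_maps.csv"

        def _assign():
            gdf = pd.read_csv(grid_csv)
            lons = np.sort(gdf["lon"].unique())
            lats = np.sort(gdf["lat"].unique())
            mean = gdf.pivot(index="lat", columns="lon", values="mean_d18O_water").to_numpy()
            sd = gdf.pivot(index="lat", columns="lon", values="sd").to_numpy()
            surface = iso.Isoscape(lons=lons, lats=lats, mean=mean, sd=sd)
            model = json.loads(oxy_model_json.read_text())
            odf = pd.read_csv(oxy_clusters_csv)
            maps, summaries = [], {}
            for j, mu in enumerate(model["means"]):
                members = odf[odf["oxygen_cluster"] == j]["d18O_water_vsmow"]
                sem = float(members.std(ddof=1) / np.sqrt(len(members))) if len(members) > 1 else cfg["assign"]["sigma_individual"]
                rm = iso.assign_residence(surface, float(mu), max(sem, 0.05))
                summaries[f"cluster_{j}"] = iso.map_summary(rm, 0.95) | {"measured": mu, "sigma": sem}
                f = rm.to_frame()
                f.insert(0, "target", f"cluster_{j}")
                maps.append(f)
            for _, row in odf[odf["oxygen_cluster"] == cl.OUTLIER].iterrows():
                rm = iso.assign_residence(
                    surface, float(row["d18O_water_vsmow"]), cfg["assign"]["sigma_individual"]
                )
                summaries[str(row["sample_id"])] = iso.map_summary(rm, 0.95) | {
                    "measured": float(row["d18O_water_vsmow"]),
                    "sigma": cfg["assign"]["sigma_individual"],
                }
                f = rm.to_frame()
                f.insert(0, "target", row["sample_id"])
                maps.append(f)
            pd.concat(maps, ignore_index=True).to_csv(assign_csv, index=False)
            summaries_slim = {
                k: {kk: vv for kk, vv in v.items() if kk != "cells"} for k, v in summaries.items()
            }
            assign_json.write_text(json.dumps(summaries_slim, indent=2, default=float))

        stage("assign", [grid_csv, oxy_clusters_csv, oxy_model_json], [assign_json, assign_csv], _assign)

    manifest.save(outdir / "manifest.json")
    return manifest
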