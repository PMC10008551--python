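"""Seeded generators emulating the statistical structure of a medieval
multi-isotope bioarchaeological assemblage.

Defaults mirror the study conditions the pipeline targets: 134 humans
and 21 fauna across three sites, ~12% collagen QC failures, two
dietary clusters (one along a C3→C4 protein mixing line, one along a
C3→marine line, in a 15:63 ratio), a resident/migrant drinking-water
δ18O mixture (57 residents around −7.7 ± 0.8‰, 5 migrants around
−12.9 ± 0.9‰, four extreme outliers) and elevated faunal δ15N
baselines.  Every generator is a pure function of (spec, seed); ground
truth is returned alongside the data and is never read by any
analysis stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mixing import MixingProblem, default_offsets, default_routing, default_sources, build_problem, ProxyTarget, forward_model
from .oxygen import convert_array, water_to_carbonate_vpdb
from .samples import IsotopeSample

__all__ = [
    "PopulationSpec",
    "default_problem_for_synthesis",
    "generate_consumers",
    "generate_fauna",
    "generate_mobility",
    "generate_isoscape_points",
    "default_field",
    "simulate_all",
]

SOURCE_ORDER = ("C3 plants", "C4 cereals", "cattle", "ovicaprid", "pig", "poultry", "marine fish")

# dietary archetype endpoints (α over SOURCE_ORDER); each cluster is a
# mixing line between the shared C3 staple diet and its endpoint
ALPHA_C3_BASE = np.array([0.55, 0.03, 0.04, 0.12, 0.18, 0.03, 0.05])
ALPHA_C4_END = np.array([0.33, 0.32, 0.04, 0.12, 0.14, 0.03, 0.02])
ALPHA_MARINE_END = np.array([0.43, 0.03, 0.04, 0.10, 0.20, 0.03, 0.17])


@dataclass(frozen=True)
class MobilitySpec:
    n: int = 66
    n_migrants: int = 5
    resident_mean: float = -7.7
    resident_sd: float = 0.8
    migrant_mean: float = -12.9
    migrant_sd: float = 0.9
    outliers: tuple[float, ...] = (-16.4, -16.5, -10.8, -5.3)


@dataclass(frozen=True)
class PopulationSpec:
    """Study-condition parameters for the synthetic assemblage."""

    n_humans: int = 134
    n_fauna: int = 21
    site_counts: tuple[tuple[str, int], ...] = (
        ("Tertiveri", 113),
        ("Montecorvino", 17),
        ("San Lorenzo", 4),
    )
    cluster_weights: tuple[float, float] = (15 / 78, 63 / 78)  # C3→C4 vs C3→marine line
    proxy_noise_sd: float = 0.35  # ‰ measurement + individual scatter per proxy
    qc_failure_rate: float = 0.12
    adult_fraction: float = 0.75
    nursing_offset: float = 0.0  # ‰ added to neonate δ15N when > 0
    mobility: MobilitySpec = MobilitySpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.qc_failure_rate < 1.0):
            raise ValueError("qc_failure_rate must be in [0, 1)")
        if sum(n for _, n in self.site_counts) != self.n_humans:
            raise ValueError("site counts must sum to n_humans")


def default_problem_for_synthesis() -> MixingProblem:
    """Seven-source problem (group-level targets are irrelevant for forward use)."""
    proxies = [
        ProxyTarget("d13C_coll", -19.0, 0.7),
        ProxyTarget("d15N", 10.0, 1.0),
        ProxyTarget("d13C_carb", -12.3, 1.2),
    ]
    return build_problem(default_sources(), proxies, default_offsets(), default_routing())


def _alpha_for(cluster: int, t: float) -> np.ndarray:
    end = ALPHA_C4_END if cluster == 0 else ALPHA_MARINE_END
    a = (1.0 - t) * ALPHA_C3_BASE + t * end
    return a / a.sum()


def generate_consumers(
    spec: PopulationSpec = PopulationSpec(),
    problem: MixingProblem | None = None,
    seed: int | None = None,
) -> tuple[list[IsotopeSample], pd.DataFrame]:
    """Synthetic human consumers plus their ground-truth diet table.

    Each individual draws a position ``t`` along its cluster's mixing
    line, gets proxies from the forward mixing model plus Gaussian
    noise of sd ``proxy_noise_sd``, and an atomic C/N ratio inside the
    accepted window — except for a ``qc_failure_rate`` fraction whose
    C/N is pushed outside it (emulating diagenesis).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    problem = problem or default_problem_for_synthesis()
    if list(problem.source_names) != list(SOURCE_ORDER):
        raise ValueError("problem sources must match the synthetic archetype order")

    sites = [s for s, n in spec.site_counts for _ in range(n)]
    samples: list[IsotopeSample] = []
    truth_rows = []
    age_pool = ("neonate", "infant", "young_juvenile", "old_juvenile")
    contexts = ("privileged_shaft", "second_church", "ordinary_cemetery")

    n_fail = rng.binomial(spec.n_humans, spec.qc_failure_rate)
    fail_idx = set(rng.choice(spec.n_humans, size=n_fail, replace=False).tolist())

    for i in range(spec.n_humans):
        cluster = int(rng.random() < spec.cluster_weights[1])  # 0 = C3→C4, 1 = C3→marine
        t = float(rng.random())
        alpha = _alpha_for(cluster, t)
        pred = forward_model(alpha, problem)
        noise = rng.normal(0.0, spec.proxy_noise_sd, size=pred.shape)
        vals = dict(zip(problem.proxy_names, pred + noise))

        age = "adult" if rng.random() < spec.adult_fraction else str(rng.choice(age_pool))
        if age == "neonate" and spec.nursing_offset > 0:
            vals["d15N"] += spec.nursing_offset

        if i in fail_idx:
            cn = 3.6 + 0.2 + rng.random() * 0.4 if rng.random() < 0.9 else 2.9 - 0.1 - rng.random() * 0.2
        else:
            cn = float(rng.uniform(3.0, 3.45))

        sid = f"SYN{i + 1:03d}"
        samples.append(
            IsotopeSample(
                sample_id=sid,
                site=sites[i],
                species="human",
                tissue="bone",
                element="rib",
                age_class=age,
                sex=str(rng.choice(["F", "M", "unknown"], p=[0.2, 0.45, 0.35])),
                burial_context=str(rng.choice(contexts, p=[0.5, 0.4, 0.1])),
                d13C_coll=float(vals["d13C_coll"]),
                d15N=float(vals["d15N"]),
                d13C_carb=float(vals.get("d13C_carb", np.nan)),
                cn_atomic=float(cn),
                pct_C=float(rng.uniform(35, 45)),
                pct_N=float(rng.uniform(12, 16)),
                collagen_yield=float(rng.uniform(2, 15)),
            )
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "cluster": cluster,
                "t": t,
                "qc_fail": i in fail_idx,
                **{f"alpha_{name}": alpha[k] for k, name in enumerate(SOURCE_ORDER)},
            }
        )
    return samples, pd.DataFrame(truth_rows)


def generate_fauna(
    spec: PopulationSpec = PopulationSpec(), seed: int | None = None
) -> list[IsotopeSample]:
    """Synthetic faunal baseline with elevated δ15N (manured/penned husbandry)."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 101)
    species_pool = ["cattle", "pig", "sheep/goat", "poultry", "horse", "deer", "tortoise"]
    base_d15N = {"cattle": 6.5, "pig": 7.0, "sheep/goat": 6.0, "poultry": 9.5, "horse": 5.5, "deer": 7.3, "tortoise": 5.5}
    out = []
    for i in range(spec.n_fauna):
        sp = species_pool[i % len(species_pool)]
        site = "Tertiveri" if i % 3 == 0 else "Montecorvino"
        d13c = float(rng.normal(-21.3 if site == "Tertiveri" else -22.0, 1.0))
        d15n = float(rng.normal(base_d15N[sp], 1.2))
        d18o_water = float(rng.uniform(-10.4, -1.7))
        out.append(
            IsotopeSample(
                sample_id=f"SYNF{i + 1:02d}",
                site=site,
                species=sp,
                tissue="bone",
                element="long bone",
                age_class="unknown",
                d13C_coll=d13c,
                d15N=d15n,
                d13C_carb=float(rng.normal(-12.1, 1.5)),
                d18O_carb_vpdb=water_to_carbonate_vpdb(d18o_water).value,
                cn_atomic=float(rng.uniform(3.0, 3.45)),
                collagen_yield=float(rng.uniform(2, 12)),
            )
        )
    return out


def generate_mobility(
    spec: PopulationSpec = PopulationSpec(), seed: int | None = None
) -> pd.DataFrame:
    """Resident/migrant/outlier δ18O structure with ground-truth labels.

    Water values are drawn per class and back-converted to carbonate
    VPDB through the exact inverse of the conversion chain, so running
    the forward chain on the emitted carbonate values reproduces the
    intended water values.
    """
    m = spec.mobility
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 202)
    n_out = len(m.outliers)
    n_res = m.n - m.n_migrants - n_out
    if n_res <= 0:
        raise ValueError("mobility spec leaves no residents")
    water = np.concatenate(
        [
            rng.normal(m.resident_mean, m.resident_sd, size=n_res),
            rng.normal(m.migrant_mean, m.migrant_sd, size=m.n_migrants),
            np.asarray(m.outliers, dtype=float),
        ]
    )
    labels = ["resident"] * n_res + ["migrant"] * m.n_migrants + ["outlier"] * n_out
    order = rng.permutation(m.n)
    df = pd.DataFrame(
        {
            "sample_id": [f"SYNM{j + 1:03d}" for j in range(m.n)],
            "true_class": np.asarray(labels, dtype=object)[order],
            "d18O_water_true": water[order],
        }
    )
    df["d18O_carb_vpdb"] = [water_to_carbonate_vpdb(w).value for w in df["d18O_water_true"]]
    return df


def default_field(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Smooth western-European-like water δ18O field (‰ VSMOW).

    A southward-enriched latitudinal gradient plus a strong depletion
    bump over the Alps; ~−7.1‰ around southern Italy, ~−14‰ in the
    high Alps.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    alpine = 5.5 * np.exp(-(((lon - 10.0) / 3.5) ** 2 + ((lat - 46.5) / 2.0) ** 2))
    return -5.0 - 0.33 * (lat - 35.0) - alpine


def generate_isoscape_points(
    field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    n: int = 200,
    seed: int = 0,
    bbox: tuple[float, float, float, float] = (-10.0, 30.0, 35.0, 60.0),
    noise_sd: float = 0.2,
) -> pd.DataFrame:
    """Point table (lon, lat, mean_d18O_water, se) sampled from a smooth field."""
    rng = np.random.default_rng(seed)
    f = field or default_field
    lon = rng.uniform(bbox[0], bbox[1], size=n)
    lat = rng.uniform(bbox[2], bbox[3], size=n)
    mean = f(lon, lat) + rng.normal(0.0, noise_sd, size=n)
    se = rng.uniform(0.2, 0.4, size=n)
    return pd.DataFrame({"lon": lon, "lat": lat, "mean_d18O_water": mean, "se": se})


def simulate_all(
    spec: PopulationSpec = PopulationSpec(),
    outdir: str | Path = "simulated",
    n_isoscape_points: int = 200,
) -> dict[str, Path]:
    """Write the full fixture set: samples, truth tables, isoscape points, spec.

    Mobility carbonate δ18O values are attached to the first adult
    humans from Tertiveri/Montecorvino so the full pipeline (QC →
    conversion → clustering → assignment) can run off one CSV.
    """
    from .samples import samples_to_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    humans, diet_truth = generate_consumers(spec)
    fauna = generate_fauna(spec)
    mobility = generate_mobility(spec)

    adult_ids = [
        s.sample_id
        for s in humans
        if s.age_class == "adult" and s.site in ("Tertiveri", "Montecorvino")
    ][: len(mobility)]
    carb_by_row = dict(zip(adult_ids, mobility["d18O_carb_vpdb"].tolist()))
    id_by_row = dict(zip(adult_ids, mobility["sample_id"].tolist()))
    for s in humans:
        if s.sample_id in carb_by_row:
            s.d18O_carb_vpdb = carb_by_row[s.sample_id]
    mobility = mobility.copy()
    rev = {v: k for k, v in id_by_row.items()}
    mobility["assigned_sample_id"] = mobility["sample_id"].map(rev)

    df = samples_to_frame(humans + fauna)
    paths = {
        "samples": outdir / "samples.csv",
        "diet_truth": outdir / "diet_truth.csv",
        "mobility_truth": outdir / "mobility_truth.csv",
        "isoscape_points": outdir / "isoscape_points.csv",
        "spec": outdir / "population_spec.json",
    }
    df.to_csv(paths["samples"], index=False)
    diet_truth.to_csv(paths["diet_truth"], index=False)
    mobility.to_csv(paths["mobility_truth"], index=False)
    generate_isoscape_points(n=n_isoscape_points, seed=spec.seed + 303).to_csv(
        paths["isoscape_points"], index=False
    )
    paths["spec"].write_text(json.dumps(asdict(spec), indent=2, default=str))
    return paths
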