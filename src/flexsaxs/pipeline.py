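"""End-to-end workflows with one-file YAML configuration.

Three bundled runs mirror how a flexible multi-domain protein is studied:

* ``run_static`` — static characterization: (optional) reduction, model-free
  invariants, ab initio envelopes with clustering/averaging, envelope-
  restrained refinement of a starting model, best-model selection by chi^2.
* ``run_flexibility`` — conformer pool, GA ensemble selection, Rflex/Rsigma.
* ``run_comparison`` — condition series (temperature or concentration x
  additive), per-condition invariants, profile PCA and size trends.

Every stochastic stage draws its seed deterministically from the config
seed, so a rerun with the same config reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import (
    comparative_stats,
    ensemble_optimization,
    envelope_modeling,
    flexible_fitting,
    profile_analysis,
    saxs_io,
    synthetic_data,
)
from .core import AtomicModel, DomainPartition, ScatteringProfile

__all__ = ["RunConfig", "run_static", "run_flexibility", "run_comparison"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-file configuration for the bundled pipelines."""

    seed: int = 0
    output_dir: str = "flexsaxs_out"
    profile_path: str | None = None
    model_path: str | None = None
    # dense low-q start so a ~60 A particle keeps >= 10 points inside the
    # Guinier window q*Rg <= 1.3
    q_min: float = 0.002
    q_max: float = 0.25
    n_q: int = 180
    surrogate: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    invariants: dict = field(default_factory=dict)
    envelope: dict = field(default_factory=dict)
    refine: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    comparison: dict = field(default_factory=dict)
    stages: list[str] | None = None  # None = all stages of the chosen run

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def stage_seed(self, offset: int) -> int:
        return int((self.seed * 1000 + offset) % (2**31 - 1))

    def q_grid(self) -> np.ndarray:
        return np.linspace(self.q_min, self.q_max, self.n_q)

    def enabled(self, stage: str) -> bool:
        return self.stages is None or stage in self.stages


def _surrogate(config: RunConfig) -> tuple[AtomicModel, DomainPartition]:
    spec = synthetic_data.SurrogateSpec(
        **{**config.surrogate, "seed": config.stage_seed(1)}
    )
    return synthetic_data.build_antibody_surrogate(spec)


def _noise(config: RunConfig, offset: int) -> synthetic_data.NoiseSpec:
    return synthetic_data.NoiseSpec(
        **{**config.noise, "seed": config.stage_seed(offset)}
    )


def _input_profile(config: RunConfig) -> tuple[ScatteringProfile, AtomicModel | None,
                                               DomainPartition | None]:
    """Measured profile plus (optionally) the starting model."""
    model = part = None
    if config.model_path:
        model, part = saxs_io.read_model_pdb(config.model_path)
    elif config.profile_path is None:
        model, part = _surrogate(config)
    if config.profile_path:
        profile = saxs_io.read_profile(config.profile_path)
    else:
        profile = synthetic_data.simulate_profile(
            model, config.q_grid(), _noise(config, 2)
        )
    return profile, model, part


def _report(config: RunConfig, name: str, payload: dict) -> dict:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{name}.json"
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
    payload["report_path"] = str(path)
    return payload


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def run_static(config: RunConfig) -> dict:
    """Static characterization: invariants -> envelopes -> restrained fit."""
    profile, model, part = _input_profile(config)
    report: dict = {"seed": config.seed}

    inv = config.invariants
    if config.enabled("invariants"):
        g = profile_analysis.guinier_fit(profile)
        report["guinier"] = {"Rg": g.Rg, "I0": g.I0, "qmax_Rg": g.qmax_Rg}
        dmax = inv.get("dmax")
        if dmax is None:
            guess = 3.5 * g.Rg
            scan = profile_analysis.scan_dmax(
                profile, np.linspace(0.6 * guess, 1.4 * guess, 9)
            )
            dmax = scan.optimal_dmax
            report["dmax_scan"] = {
                "grid": scan.dmax_grid,
                "scores": scan.scores,
                "suggested_qmax": scan.suggested_qmax,
            }
        pr = profile_analysis.ift_pr(profile, dmax, alpha=inv.get("alpha"))
        report["pr"] = {
            "Dmax": pr.Dmax,
            "Rg": pr.Rg,
            "I0": pr.I0,
            "alpha": pr.alpha,
            "chi2_reduced": pr.chi2_reduced,
            "peaks": profile_analysis.pr_peaks(pr),
        }
    else:
        pr = None

    env_cfg = config.envelope
    grid = None
    if config.enabled("envelope"):
        n_models = int(env_cfg.get("n_models", 8))
        target = pr if pr is not None else profile
        # search sphere 15% beyond the P(r) Dmax (the IFT tends to clip the
        # faint tail of elongated particles); beads only occupy what the
        # data demand.  Coarser beads than the library default keep a
        # multi-model run interactive.
        dmax_env = env_cfg.get("dmax", 1.15 * pr.Dmax if pr else None)
        kwargs = dict(
            bead_radius=env_cfg.get(
                "bead_radius", dmax_env / 16.0 if dmax_env else None
            ),
            dmax=dmax_env,
        )
        envelopes = [
            envelope_modeling.anneal_envelope(
                target, seed=config.stage_seed(10 + i), **kwargs
            )
            for i in range(n_models)
        ]
        if n_models >= 2:
            clust = envelope_modeling.cluster_envelopes(
                envelopes, linkage_threshold=env_cfg.get("cluster_threshold", 0.7)
            )
            sizes = {lab: len(m) for lab, m in clust.cluster_members.items()}
            report["envelope_clusters"] = {
                "sizes": sizes,
                "isolated": clust.isolated,
            }
            if clust.cluster_members:
                biggest = max(clust.cluster_members, key=lambda k: len(clust.cluster_members[k]))
                ref_i = clust.cluster_members[biggest][0]
                members = [
                    envelope_modeling.align_models(envelopes[i], envelopes[ref_i])
                    if i != ref_i
                    else envelopes[i]
                    for i in clust.cluster_members[biggest]
                ]
            else:  # all isolated: fall back to the best-objective model
                members = [envelopes[0]]
            avg, _freq = envelope_modeling.average_envelopes(members)
        else:
            avg = envelopes[0]
        report["envelope"] = {
            "n_beads": len(avg),
            "bead_radius": avg.bead_radius,
            "rg": avg.rg(),
        }
        grid = envelope_modeling.voxelize(
            avg,
            spacing=env_cfg.get("grid_spacing", 3.0),
            blur_sigma=env_cfg.get("blur_sigma", 8.0),
        )

    if config.enabled("refine") and model is not None and grid is not None:
        ref_cfg = config.refine
        # the ab initio envelope lives in its own (lattice) frame: rigidly
        # dock the starting model into it before local refinement
        model = envelope_modeling.align_models(model, avg)
        net = flexible_fitting.build_restraint_network(
            model, part, cutoff=ref_cfg.get("cutoff", 12.0),
            spring_k=ref_cfg.get("spring_k", 1.0),
        )
        traj = flexible_fitting.restrained_refine(
            model,
            grid,
            net,
            flexible_fitting.EnvelopePotentialParams(k=ref_cfg.get("k", 0.1)),
            steps=int(ref_cfg.get("steps", 1500)),
            step_size=ref_cfg.get("step_size", 0.3),
            temperature=ref_cfg.get("temperature", 0.0),
            seed=config.stage_seed(30),
            profile=profile,
            stride=int(ref_cfg.get("stride", 100)),
            rigid_domains=part if ref_cfg.get("rigid_domains", True) else None,
        )
        coords, frame, chi2 = flexible_fitting.select_best_model(traj)
        best = model.with_coords(coords)
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        saxs_io.write_model_pdb(out / "best_model.pdb", best, part)
        report["refine"] = {
            "chi2_trace": traj.chi2,
            "envelope_corr_trace": traj.envelope_corr,
            "rg_trace": traj.rg,
            "best_frame": frame,
            "best_chi2": chi2,
            "best_model": str(out / "best_model.pdb"),
        }
    return _report(config, "static_report", report)


def run_flexibility(config: RunConfig) -> dict:
    """Pool generation, ensemble selection, flexibility quantification."""
    profile, model, part = _input_profile(config)
    if model is None:
        model, part = _surrogate(config)
    ens = config.ensemble
    spec = synthetic_data.SurrogateSpec(**config.surrogate) if config.surrogate else synthetic_data.SurrogateSpec()
    hinge_ranges = ens.get("hinge_ranges", spec.hinge_angle_ranges)
    pool = ensemble_optimization.build_pool(
        model,
        part,
        hinge_ranges,
        int(ens.get("pool_size", 200)),
        profile.q,
        seed=config.stage_seed(40),
    )
    selection = ensemble_optimization.select_ensemble(
        pool,
        profile,
        ensemble_size=int(ens.get("ensemble_size", 10)),
        seed=config.stage_seed(41),
    )
    metrics, curves = ensemble_optimization.flexibility_report(
        pool, selection, n_bins=int(ens.get("bins", 20))
    )
    report = {
        "seed": config.seed,
        "pool_size": len(pool),
        "selected_members": selection.members,
        "weights": selection.weights,
        "chi2": selection.chi2,
        "rflex_selected_pct": metrics.rflex_selected,
        "rflex_pool_pct": metrics.rflex_pool,
        "rsigma": metrics.rsigma,
        "histograms": curves,
    }
    return _report(config, "flexibility_report", report)


def run_comparison(config: RunConfig) -> dict:
    """Condition comparison: invariants per condition, PCA, size trends."""
    cmp_cfg = config.comparison
    model, part = _surrogate(config)
    q = config.q_grid()
    conditions: dict[str, list[ScatteringProfile]] = {}
    replicate_sets: dict[str, list[list[ScatteringProfile]]] = {}
    if "profile_dirs" in cmp_cfg:
        for name, d in cmp_cfg["profile_dirs"].items():
            conditions[name] = [
                saxs_io.read_profile(f) for f in sorted(Path(d).glob("*.dat"))
            ]
    else:
        concentrations = cmp_cfg.get(
            "concentrations", [1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        )
        n_rep = int(cmp_cfg.get("replicates", 3))
        for i, (name, fn) in enumerate(
            {
                "aggregating": synthetic_data.default_dimer_fraction,
                "non_aggregating": lambda c: 0.0,
            }.items()
        ):
            replicate_sets[name] = [
                synthetic_data.simulate_concentration_series(
                    model,
                    concentrations,
                    q,
                    dimer_fraction_fn=fn,
                    noise=_noise(config, 50 + 10 * i + rep),
                    seed=config.stage_seed(60 + 10 * i + rep),
                )
                for rep in range(n_rep)
            ]
            conditions[name] = replicate_sets[name][0]
    if len(conditions) < 2:
        raise ValueError("comparison needs at least two condition series")

    report: dict = {"seed": config.seed, "conditions": {}}
    all_profiles: list[ScatteringProfile] = []

    def _rows(profs: list[ScatteringProfile]) -> list[dict]:
        rows = []
        for p in profs:
            g = profile_analysis.guinier_fit(p)
            rows.append(
                {
                    "concentration": p.metadata.get("concentration"),
                    "temperature": p.metadata.get("temperature"),
                    "rg": g.Rg,
                    "i0": g.I0,
                }
            )
        return rows

    for name, profs in conditions.items():
        rows = _rows(profs)
        entry: dict = {"invariants": rows}
        if all(r["concentration"] is not None for r in rows) and len(rows) >= 3:
            entry["size_trend"] = comparative_stats.size_vs_concentration(rows)
            reps = replicate_sets.get(name)
            if reps and len(reps) > 1:
                trends = [
                    comparative_stats.size_vs_concentration(_rows(rp))["rg"]
                    for rp in reps
                ]
                entry["size_trend_replicates"] = trends
                entry["size_trend"]["rg_mean"] = float(
                    np.mean([t for t in trends if t is not None])
                )
        report["conditions"][name] = entry
        all_profiles.extend(profs)
    mat, meta, excluded = comparative_stats.profile_matrix(all_profiles)
    res = comparative_stats.pca(mat, center=True, scale=False)
    report["profile_pca"] = {
        "explained": res.explained,
        "pc1_scores": res.scores[:, 0],
        "excluded": excluded,
        "labels": [m.get("concentration") for m in meta],
    }
    return _report(config, "comparison_report", report)
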