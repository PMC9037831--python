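"""Ensemble selection against a SAXS profile and flexibility metrics.

A pool of rigid-domain conformers is searched with a genetic algorithm for
the sub-ensemble (multiset) whose uniformly weighted mean profile best fits
the data (chi^2 with a fitted scale).  Comparing the size distribution of
the selected ensemble with that of the random pool quantifies flexibility:

* Rflex: Shannon entropy of the binned Rg (or Dmax) distribution as a
  percentage of the maximum possible entropy — 100% for a fully flexible
  system whose selected sizes spread over all bins, 0% for a rigid one.
* Rsigma: ratio of the standard deviation of the selected ensemble's sizes
  to the pool's; < 1 means selection narrowed the distribution (rigidity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AtomicModel, DomainPartition, ScatteringProfile
from .forward_scattering import debye_profile
from .synthetic_data import sample_conformers

__all__ = [
    "ConformerPool",
    "EnsembleSelection",
    "FlexibilityMetrics",
    "GAParams",
    "build_pool",
    "select_ensemble",
    "rflex",
    "rsigma",
    "flexibility_report",
]

log = logging.getLogger(__name__)


@dataclass
class ConformerPool:
    """Conformers with precomputed profiles and size metrics."""

    models: list[AtomicModel]
    q: np.ndarray
    profiles: np.ndarray  # (n_models, n_q)
    rg: np.ndarray
    dmax: np.ndarray

    def __len__(self) -> int:
        return len(self.models)


@dataclass
class EnsembleSelection:
    members: np.ndarray  # unique member indices
    weights: np.ndarray  # multiplicity / ensemble_size, sums to 1
    chi2: float
    ensemble_size: int
    fitness_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.members) != len(np.unique(self.members)):
            raise ValueError("member indices must be unique")
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


@dataclass
class FlexibilityMetrics:
    rflex_selected: float  # percent
    rflex_pool: float  # percent
    rsigma: float


@dataclass
class GAParams:
    population: int = 100
    generations: int = 200
    mutation_rate: float = 0.1
    tournament: int = 5
    elitism: int = 1
    patience: int = 60


def build_pool(
    template: AtomicModel,
    partition: DomainPartition,
    hinge_ranges: Mapping[str, Mapping[str, tuple[float, float]]],
    n: int,
    q_grid: np.ndarray,
    seed: int = 0,
) -> ConformerPool:
    """Sample n conformers and precompute per-model profiles, Rg, Dmax."""
    if n < 2:
        raise ValueError("a pool needs at least 2 conformers")
    models = sample_conformers(template, partition, hinge_ranges, n, seed=seed)
    q = np.asarray(q_grid, dtype=float)
    profs = np.stack(
        [debye_profile(mdl, q, form_factor_mode="model").I for mdl in models]
    )
    rg = np.array([mdl.rg() for mdl in models])
    dmax = np.array([mdl.dmax() for mdl in models])
    return ConformerPool(models=models, q=q, profiles=profs, rg=rg, dmax=dmax)


def _ensemble_chi2(
    mean_profile: np.ndarray, I_obs: np.ndarray, w: np.ndarray
) -> float:
    den = float(np.sum(w * mean_profile**2))
    c = float(np.sum(w * I_obs * mean_profile)) / den if den > 0 else 0.0
    r = I_obs - c * mean_profile
    return float(np.sum(w * r * r) / max(len(I_obs) - 1, 1))


def select_ensemble(
    pool: ConformerPool,
    obs: ScatteringProfile,
    ensemble_size: int = 5,
    ga: GAParams | None = None,
    seed: int = 0,
) -> EnsembleSelection:
    """Genetic-algorithm search for the best-fitting sub-ensemble.

    Chromosomes are multisets of ``ensemble_size`` pool indices; fitness is
    the chi^2 between the observation and the uniform mean of the member
    profiles with a freely fitted scale.  Tournament selection, one-point
    member-exchange crossover, member-replacement mutation, elitism.
    Deterministic for a fixed seed.
    """
    ga = ga or GAParams()
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if len(pool) <= ensemble_size:
        raise ValueError("pool must be larger than the ensemble")
    if not np.array_equal(pool.q, obs.q):
        raise ValueError("pool and observation must share the q grid")
    rng = np.random.default_rng(seed)
    w = 1.0 / obs.sigma**2
    n_pool = len(pool)

    popn = rng.integers(0, n_pool, size=(ga.population, ensemble_size))

    def fitness(chrom: np.ndarray) -> float:
        return _ensemble_chi2(pool.profiles[chrom].mean(axis=0), obs.I, w)

    fits = np.array([fitness(c) for c in popn])
    best_trace = [float(fits.min())]
    stall = 0
    for _ in range(ga.generations):
        order = np.argsort(fits)
        new = [popn[order[i]].copy() for i in range(ga.elitism)]
        while len(new) < ga.population:
            # tournament selection of two parents
            cand = rng.integers(0, ga.population, size=ga.tournament)
            p1 = popn[cand[np.argmin(fits[cand])]]
            cand = rng.integers(0, ga.population, size=ga.tournament)
            p2 = popn[cand[np.argmin(fits[cand])]]
            cut = int(rng.integers(1, ensemble_size)) if ensemble_size > 1 else 0
            child = np.concatenate([p1[:cut], p2[cut:]])
            mut = rng.random(ensemble_size) < ga.mutation_rate
            child[mut] = rng.integers(0, n_pool, size=int(mut.sum()))
            new.append(child)
        popn = np.stack(new)
        fits = np.array([fitness(c) for c in popn])
        gen_best = float(fits.min())
        if gen_best < best_trace[-1] - 1e-12:
            stall = 0
        else:
            stall += 1
        best_trace.append(min(gen_best, best_trace[-1]))
        if stall >= ga.patience:
            break
    converged = stall < ga.patience
    if not converged:
        log.warning("GA stalled for %d generations; returning best-so-far", stall)
    best = popn[int(np.argmin(fits))]
    members, counts = np.unique(best, return_counts=True)
    return EnsembleSelection(
        members=members,
        weights=counts / ensemble_size,
        chi2=float(fits.min()),
        ensemble_size=ensemble_size,
        fitness_trace=np.array(best_trace),
        converged=converged,
    )


def rflex(values: Sequence[float], bin_edges: np.ndarray) -> float:
    """Entropy-based flexibility percentage of a size distribution.

    Rflex = 100 * H(p) / log2(n_bins) with H the Shannon entropy of the
    histogram probabilities over fixed bins (0 log 0 := 0).
    """
    values = np.asarray(values, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    if bin_edges.size < 3 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("need >= 2 strictly increasing bins")
    counts, _ = np.histogram(values, bins=bin_edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("all values fall outside the bins")
    p = counts[counts > 0] / total
    entropy = float(-np.sum(p * np.log2(p)))
    return 100.0 * entropy / np.log2(len(bin_edges) - 1)


def rsigma(selected: Sequence[float], pool: Sequence[float]) -> float:
    """sd(selected) / sd(pool); < 1 flags a narrowed (rigid) selection."""
    selected = np.asarray(selected, dtype=float)
    pool = np.asarray(pool, dtype=float)
    if selected.size < 2 or pool.size < 2:
        raise ValueError("need >= 2 values in both sets")
    sd_pool = float(np.std(pool, ddof=1))
    if sd_pool == 0:
        raise ValueError("pool has zero size spread")
    return float(np.std(selected, ddof=1)) / sd_pool


def flexibility_report(
    pool: ConformerPool,
    selection: EnsembleSelection,
    n_bins: int = 20,
    metric: str = "rg",
) -> tuple[FlexibilityMetrics, dict]:
    """Rflex/Rsigma plus the weighted size histograms behind them.

    Bins span the pool's [min, max] of the chosen size metric; the
    selected-ensemble histogram weighs members by their selection weights.
    """
    vals_pool = pool.rg if metric == "rg" else pool.dmax
    if metric not in ("rg", "dmax"):
        raise ValueError("metric must be 'rg' or 'dmax'")
    edges = np.linspace(vals_pool.min(), vals_pool.max() * (1 + 1e-12), n_bins + 1)
    sel_vals = vals_pool[selection.members]
    # weighted selected values: expand by multiplicity for entropy/sd
    mult = np.rint(selection.weights * selection.ensemble_size).astype(int)
    expanded = np.repeat(sel_vals, np.maximum(mult, 1))
    met = FlexibilityMetrics(
        rflex_selected=rflex(expanded, edges),
        rflex_pool=rflex(vals_pool, edges),
        rsigma=rsigma(expanded, vals_pool) if expanded.size >= 2 else 0.0,
    )
    hist_pool, _ = np.histogram(vals_pool, bins=edges, density=True)
    hist_sel, _ = np.histogram(sel_vals, bins=edges, weights=selection.weights,
                               density=True)
    curves = {
        "bin_edges": edges,
        "pool_density": hist_pool,
        "selected_density": hist_sel,
        "metric": metric,
    }
    return met, curves
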