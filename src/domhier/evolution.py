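"""Generation loop and replicate management.

One generation of the life cycle: each group forms a dominance hierarchy
through learned contests; each competing individual then risks dying from
accumulated damage; survivors acquire resources subject to interference and
parenting costs; the census number of offspring is allocated multinomially
across survivors (local/global competition mix plus the outside option);
offspring inherit Mendelian alleles from their two parents, mutate, and
disperse globally by random permutation into the groups of the next
generation.  Fresh qualities are drawn for the new competing sex.

A replicate is a sequence of generations from a monomorphic founder
population, driven by a single random stream derived from one master seed,
so replicates are reproducible independently and in parallel.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import genetics, hierarchy, reproduction, summaries
from .genetics import PopulationState
from .params import N_LOCI, TRAIT_NAMES, Parameters
from .reproduction import ExtinctionError

logger = logging.getLogger("domhier")

__all__ = ["GenerationSummary", "ReplicateSummary", "replicate_rng",
           "run_generation", "run_simulation", "run_replicates",
           "trajectory_frame"]


@dataclass
class GenerationSummary:
    """Light per-generation statistics (Fig-2-shaped aggregates)."""

    generation: int
    trait_means: np.ndarray          # (N_LOCI,) mean expressed traits, competing sex
    aa_per_group: float              # mean AA (fighting) rounds per group
    mean_damage: float
    n_deaths: int
    n_survivors: int
    skew_q1: float
    skew_median: float
    skew_q3: float
    per_rank_rs: np.ndarray          # (S,) mean realized RS by survivor rank
    per_rank_expected_rs: np.ndarray
    decomposition: np.ndarray        # (3,) remaining / lost_interference / lost_damage


@dataclass
class ReplicateSummary:
    """Across-replicate aggregate of evolved traits and outcomes.

    ``traits_mean``/``traits_sd`` are mean and s.d. over replicates of each
    replicate's equilibrium read-out (the population-mean expressed traits
    averaged over the final ``summary_window`` generations).  The s.d. is
    NaN for a single replicate.
    """

    traits_mean: np.ndarray
    traits_sd: np.ndarray
    per_replicate: np.ndarray        # (replicates, N_LOCI)
    aa_per_group_mean: float         # over replicates, of window-mean AA per group
    skew_median_mean: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trait": list(TRAIT_NAMES),
            "mean": self.traits_mean,
            "sd": self.traits_sd,
        })


def replicate_rng(master_seed: int, replicate: int = 0) -> np.random.Generator:
    """The single random stream of one replicate.

    Derived from the master seed with the replicate index as spawn key, so
    any replicate can be reproduced without running the others.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))


def run_generation(state: PopulationState, p: Parameters, rng: np.random.Generator,
                   collect_records: bool = False,
                   ) -> Tuple[PopulationState, GenerationSummary, Optional[List[summaries.GroupRecord]]]:
    """Advance the population one generation.

    Returns the next state, the generation summary and (optionally) per-group
    raw outcome records.  The census is conserved exactly.  Raises
    :class:`ExtinctionError` if no competing-sex individual survives.
    """
    G, S = state.comp_q.shape
    So = state.other_alleles.shape[1]
    traits = state.comp_traits()

    # 1. contests and hierarchy
    log, _learning = hierarchy.run_contest_phase(state.comp_q, traits, p, rng)
    ranks = hierarchy.assign_dominance_positions(log, rng)

    # 2. mortality from damage
    mu = reproduction.mortality_probability(log.damage, p)
    alive = rng.random(size=(G, S)) >= mu
    n_survivors = int(alive.sum())
    if n_survivors == 0:
        raise ExtinctionError(f"population extinct at generation {state.generation}")

    # 3. acquired resources and offspring allocation
    kappa = traits[..., genetics.LOCUS["kappa"]]
    outcome = reproduction.compute_effective_AR(ranks, kappa, log.damage, alive, p)
    counts = reproduction.allocate_offspring(outcome, alive, p, rng)

    # 4. summary statistics (survivors only hold dominance positions)
    m_groups = summaries.skew_index_M_groups(counts, alive)
    finite_m = m_groups[~np.isnan(m_groups)]
    if finite_m.size:
        q1, med, q3 = np.percentile(finite_m, [25, 50, 75], method="linear")
    else:
        q1 = med = q3 = float("nan")
    per_rank_rs = np.full(S, np.nan)
    per_rank_ers = np.full(S, np.nan)
    sr = outcome.survivor_rank
    for k in range(1, S + 1):
        sel = sr == k
        if sel.any():
            per_rank_rs[k - 1] = counts[sel].mean()
            per_rank_ers[k - 1] = outcome.expected_rs[sel].mean()
    summary = GenerationSummary(
        generation=state.generation,
        trait_means=traits.reshape(-1, N_LOCI).mean(axis=0),
        aa_per_group=log.total_aa / G,
        mean_damage=float(log.damage.mean()),
        n_deaths=G * S - n_survivors,
        n_survivors=n_survivors,
        skew_q1=float(q1), skew_median=float(med), skew_q3=float(q3),
        per_rank_rs=per_rank_rs,
        per_rank_expected_rs=per_rank_ers,
        decomposition=outcome.decomposition.mean(axis=0),
    )

    records = None
    if collect_records:
        records = []
        for g in range(G):
            sel = alive[g]
            records.append(summaries.GroupRecord(
                ranks=sr[g][sel].copy(),
                rs=counts[g][sel].copy(),
                damage=log.damage[g][sel].copy(),
                aa_rounds=log.aa_rounds[g][sel].copy(),
                M=float(m_groups[g]),
                decomposition=outcome.decomposition[g].copy(),
                generation=state.generation, group=g,
            ))

    # 5. offspring: inheritance, mutation, global dispersal
    T = G * (S + So)
    parent_flat = np.repeat(np.arange(G * S), counts.ravel())
    comp_flat = state.comp_alleles.reshape(G * S, N_LOCI, 2)
    parent_group = parent_flat // S
    other_idx = rng.integers(0, So, size=T)
    other_parent = state.other_alleles[parent_group, other_idx]
    child = genetics.recombine(comp_flat[parent_flat], other_parent, rng)
    child = genetics.mutate_alleles(child, p, rng)
    perm = rng.permutation(T)
    n_comp = G * S
    new_state = PopulationState(
        generation=state.generation + 1,
        comp_alleles=child[perm[:n_comp]].reshape(G, S, N_LOCI, 2),
        other_alleles=child[perm[n_comp:]].reshape(G, So, N_LOCI, 2),
        comp_q=rng.normal(0.0, p.sigma_q, size=(G, S)),
    )
    return new_state, summary, records


def run_simulation(p: Parameters, seed: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   collect_final_records: int = 0,
                   ) -> Tuple[List[GenerationSummary], PopulationState, List[summaries.GroupRecord]]:
    """Run one replicate: ``p.generations`` generations from founders.

    Deterministic given the seed (default ``p.seed``).  If
    ``collect_final_records > 0``, raw group records are kept for that many
    terminal generations (for Fig-2/3-style outcome tables).
    """
    if rng is None:
        rng = replicate_rng(p.seed if seed is None else seed)
    state = genetics.init_population(p, rng)
    trajectory: List[GenerationSummary] = []
    final_records: List[summaries.GroupRecord] = []
    t0 = time.perf_counter()
    for gen in range(p.generations):
        collect = gen >= p.generations - collect_final_records
        state, summary, records = run_generation(state, p, rng, collect_records=collect)
        trajectory.append(summary)
        if records is not None:
            final_records.extend(records)
        if logger.isEnabledFor(logging.INFO) and (gen + 1) % 100 == 0:
            dt = time.perf_counter() - t0
            logger.info("generation %d/%d (%.2f s/gen, mean kappa %.3f)",
                        gen + 1, p.generations, dt / (gen + 1),
                        summary.trait_means[genetics.LOCUS["kappa"]])
    return trajectory, state, final_records


def equilibrium_traits(trajectory: Sequence[GenerationSummary], window: int) -> np.ndarray:
    """Population-mean traits averaged over the final ``window`` generations."""
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    window = max(1, min(window, len(trajectory)))
    return np.mean([s.trait_means for s in trajectory[-window:]], axis=0)


def run_replicates(p: Parameters, n_jobs: int = 1) -> ReplicateSummary:
    """Run ``p.replicates`` independent replicates and aggregate.

    Replicate r uses the stream ``replicate_rng(p.seed, r)``; adding or
    removing other replicates does not change r's result.
    """
    per_rep = np.empty((p.replicates, N_LOCI))
    aa_means = np.empty(p.replicates)
    skew_meds = np.empty(p.replicates)
    for r in range(p.replicates):
        traj, _state, _rec = run_simulation(p, rng=replicate_rng(p.seed, r))
        per_rep[r] = equilibrium_traits(traj, p.summary_window)
        w = max(1, min(p.summary_window, len(traj)))
        aa_means[r] = np.mean([s.aa_per_group for s in traj[-w:]])
        skew_meds[r] = np.nanmean([s.skew_median for s in traj[-w:]])
        logger.info("replicate %d/%d done", r + 1, p.replicates)
    sd = per_rep.std(axis=0, ddof=1) if p.replicates > 1 else np.full(N_LOCI, np.nan)
    return ReplicateSummary(
        traits_mean=per_rep.mean(axis=0),
        traits_sd=sd,
        per_replicate=per_rep,
        aa_per_group_mean=float(aa_means.mean()),
        skew_median_mean=float(np.nanmean(skew_meds)),
    )


def trajectory_frame(trajectory: Sequence[GenerationSummary]) -> pd.DataFrame:
    """Trajectory as a tidy frame: one row per generation."""
    rows = []
    for s in trajectory:
        row = {"generation": s.generation}
        row.update({f"mean_{n}": s.trait_means[i] for i, n in enumerate(TRAIT_NAMES)})
        row.update({
            "aa_per_group": s.aa_per_group,
            "mean_damage": s.mean_damage,
            "n_deaths": s.n_deaths,
            "n_survivors": s.n_survivors,
            "skew_median": s.skew_median,
            "skew_q1": s.skew_q1,
            "skew_q3": s.skew_q3,
            "ar_remaining": s.decomposition[0],
            "ar_lost_interference": s.decomposition[1],
            "ar_lost_damage": s.decomposition[2],
        })
        rows.append(row)
    return pd.DataFrame(rows)
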