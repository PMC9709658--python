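"""Post-contest phase: mortality, acquired resources and offspring allocation.

After the hierarchy is formed, each competing individual risks dying from
accumulated contest damage.  Survivors then acquire contested resources (AR)
for reproduction:

* a baseline AR decays exponentially with dominance position (the hierarchy
  imposes a baseline reproductive skew);
* every living higher-ranked groupmate interferes, multiplicatively retaining
  only a fraction ``1 - phi*(1 - exp(-b1*kappa))`` of a subordinate's AR;
* performing interference costs the dominant a fraction of its own AR
  (``1 - b0*(1 - exp(-b1*kappa))``, paid once regardless of targets);
* accumulated damage reduces parenting ability by ``exp(-c2*d)``.

Offspring are then allocated one at a time (multinomially).  With
probability Q an offspring comes from uncontested outside-option
reproduction (parent drawn population-wide, weighted by parenting ability).
Otherwise it is contested: a group is chosen with weight
``lambda_local/G' + (1-lambda_local) * A_g / sum_h A_h`` (soft vs hard
selection mix over the G' groups with survivors), then the parent within the
group proportionally to effective AR.  The other-sex parent is uniform in
the chosen parent's group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import Parameters


class ExtinctionError(RuntimeError):
    """Raised when no competing-sex survivor exists population-wide."""


# ---------------------------------------------------------------------------
# elementary curves
# ---------------------------------------------------------------------------

def mortality_probability(d, p: Parameters):
    """Probability of dying from accumulated damage: min(1, c1*d), applied
    once per generation after hierarchy formation."""
    return np.minimum(1.0, p.c1 * np.asarray(d, dtype=float))


def parenting_factor(d, p: Parameters):
    """Proportional parenting ability remaining after damage: exp(-c2*d)."""
    return np.exp(-p.c2 * np.asarray(d, dtype=float))


def interference_retention(kappa_dominant, p: Parameters):
    """Fraction of a subordinate's AR retained against ONE dominant with
    interference strength kappa: 1 - phi*(1 - exp(-b1*kappa)), in [1-phi, 1]."""
    return 1.0 - p.phi * (1.0 - np.exp(-p.b1 * np.asarray(kappa_dominant, dtype=float)))


def interference_cost(kappa_self, p: Parameters):
    """Fraction of a dominant's own AR retained after paying the cost of
    interfering: 1 - b0*(1 - exp(-b1*kappa)), in [1-b0, 1]; paid once,
    regardless of the number of targets."""
    return 1.0 - p.b0 * (1.0 - np.exp(-p.b1 * np.asarray(kappa_self, dtype=float)))


def baseline_resources(rank, p: Parameters):
    """Baseline AR of dominance position k (1 = top): exp(-rho*(k-1))."""
    rank = np.asarray(rank)
    if np.any(rank < 1):
        raise ValueError("ranks start at 1")
    return np.exp(-p.baseline_decay_rho * (rank - 1.0))


def group_max_resources(p: Parameters) -> float:
    """Maximal possible group AR: sum of baseline AR over a full group."""
    return float(baseline_resources(np.arange(1, p.group_size + 1), p).sum())


# ---------------------------------------------------------------------------
# effective AR
# ---------------------------------------------------------------------------

@dataclass
class ReproductiveOutcome:
    """Per-individual AR bookkeeping and the group AR decomposition.

    All arrays are (G, S) in member order; dead members have zero effective
    AR and factor 1 placeholders.  ``decomposition`` is (G, 3): proportions
    of the maximal group AR that remain, are lost to interference (including
    its self-cost), and are lost to damage (reduced parenting).  The three
    parts sum to 1 for a full group; with deaths the sum falls short by the
    dead members' baseline share.
    """

    baseline: np.ndarray
    retention: np.ndarray
    self_cost: np.ndarray
    parenting: np.ndarray
    effective_ar: np.ndarray
    survivor_rank: np.ndarray          # recompacted rank among survivors (0 = dead)
    decomposition: np.ndarray          # (G, 3): remaining, lost_interference, lost_damage
    expected_rs: Optional[np.ndarray] = None
    offspring: Optional[np.ndarray] = None


def compute_effective_AR(ranks: np.ndarray, kappa: np.ndarray, damage: np.ndarray,
                         alive: np.ndarray, p: Parameters) -> ReproductiveOutcome:
    """Effective AR for survivors of a batch of groups.

    ``ranks`` (G, S) are pre-mortality dominance positions (a permutation of
    1..S per group); survivors keep their relative order and occupy
    recompacted positions 1..n_survivors, which determine their baseline AR.
    The survivor at recompacted position k gets

        a(k) * cost(kappa_k) * prod_{m alive, pos(m) < k} retention(kappa_m)
             * parenting(damage_k).
    """
    ranks = np.asarray(ranks)
    G, S = ranks.shape
    check = np.sort(ranks, axis=1)
    if not np.array_equal(check, np.broadcast_to(np.arange(1, S + 1), (G, S))):
        raise ValueError("ranks must be a permutation of 1..group_size per group")
    alive = np.asarray(alive, dtype=bool)

    order = np.argsort(ranks, axis=1, kind="stable")     # member indices, best rank first
    alive_o = np.take_along_axis(alive, order, axis=1)
    kappa_o = np.take_along_axis(np.asarray(kappa, dtype=float), order, axis=1)
    dmg_o = np.take_along_axis(np.asarray(damage, dtype=float), order, axis=1)

    pos = np.cumsum(alive_o, axis=1)                     # recompacted survivor rank
    a_o = np.where(alive_o, np.exp(-p.baseline_decay_rho * (pos - 1.0)), 0.0)
    s_o = np.where(alive_o, interference_retention(kappa_o, p), 1.0)
    # product of retention factors of all living, better-ranked members
    cum = np.cumprod(s_o, axis=1)
    retention_o = np.concatenate([np.ones((G, 1)), cum[:, :-1]], axis=1)
    cost_o = np.where(alive_o, interference_cost(kappa_o, p), 1.0)
    par_o = np.where(alive_o, parenting_factor(dmg_o, p), 1.0)
    eff_o = a_o * cost_o * retention_o * par_o

    total_max = group_max_resources_like(S, p)
    remaining = eff_o.sum(axis=1) / total_max
    lost_interf = (a_o * (1.0 - cost_o * retention_o)).sum(axis=1) / total_max
    lost_damage = (a_o * cost_o * retention_o * (1.0 - par_o)).sum(axis=1) / total_max
    decomposition = np.stack([remaining, lost_interf, lost_damage], axis=1)

    out = ReproductiveOutcome(
        baseline=_scatter(a_o, order),
        retention=_scatter(retention_o, order),
        self_cost=_scatter(cost_o, order),
        parenting=_scatter(par_o, order),
        effective_ar=_scatter(eff_o, order),
        survivor_rank=_scatter(np.where(alive_o, pos, 0), order).astype(int),
        decomposition=decomposition,
    )
    return out


def group_max_resources_like(S: int, p: Parameters) -> float:
    return float(np.exp(-p.baseline_decay_rho * np.arange(S)).sum())


def _scatter(values_ordered: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Undo the rank ordering: place ordered values back in member order."""
    out = np.empty_like(values_ordered)
    np.put_along_axis(out, order, values_ordered, axis=1)
    return out


# ---------------------------------------------------------------------------
# offspring allocation
# ---------------------------------------------------------------------------

def parent_probabilities(outcome: ReproductiveOutcome, alive: np.ndarray,
                         p: Parameters) -> np.ndarray:
    """Per-individual probability of parenting any one offspring, shape (G, S).

    Mixes the outside option (weight Q, parenting-ability-weighted among all
    survivors) with contested reproduction (weight 1-Q, the local/global
    group-weight mixture, then effective AR within the group).
    """
    alive = np.asarray(alive, dtype=bool)
    if not alive.any():
        raise ExtinctionError("no competing-sex survivors")
    eff = np.where(alive, outcome.effective_ar, 0.0)
    A_g = eff.sum(axis=1)                                # (G,)
    has_surv = alive.any(axis=1)
    G_prime = int(has_surv.sum())

    # within-group contested share (uniform fallback if a group's AR is 0)
    n_alive = alive.sum(axis=1)
    within = np.zeros_like(eff)
    pos_ar = A_g > 0
    within[pos_ar] = eff[pos_ar] / A_g[pos_ar, None]
    degenerate = has_surv & ~pos_ar
    if degenerate.any():
        within[degenerate] = alive[degenerate] / n_alive[degenerate, None]

    total_ar = A_g.sum()
    local_w = np.where(has_surv, 1.0 / G_prime, 0.0)
    if total_ar > 0:
        global_w = A_g / total_ar
    else:
        global_w = local_w
    wg = p.lambda_local * local_w + (1.0 - p.lambda_local) * global_w
    contested = wg[:, None] * within

    if p.outside_option_uniform:
        weights = alive.astype(float)
    else:
        weights = np.where(alive, outcome.parenting, 0.0)
    wsum = weights.sum()
    outside = weights / wsum if wsum > 0 else alive / alive.sum()

    return p.Q * outside + (1.0 - p.Q) * contested


def allocate_offspring(outcome: ReproductiveOutcome, alive: np.ndarray,
                       p: Parameters, rng: np.random.Generator,
                       n_offspring: Optional[int] = None) -> np.ndarray:
    """Realized offspring counts per competing-sex survivor, shape (G, S).

    The population's total offspring number equals the census,
    n_groups*(group_size+other_sex_size), drawn multinomially from
    :func:`parent_probabilities`, so counts sum to it exactly.  Fills
    ``outcome.expected_rs`` and ``outcome.offspring``.
    """
    G, S = outcome.effective_ar.shape
    if n_offspring is None:
        n_offspring = G * (S + p.other_sex_size)
    probs = parent_probabilities(outcome, alive, p)
    flat = probs.ravel()
    flat = flat / flat.sum()                             # guard rounding
    counts = rng.multinomial(n_offspring, flat).reshape(G, S)
    outcome.expected_rs = probs * n_offspring
    outcome.offspring = counts
    return counts
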