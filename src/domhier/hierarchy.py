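"""Within-generation contest phase: hierarchy formation by learning.

Group members meet in pairwise rounds.  In a round each contestant privately
observes the pair's relative fighting ability with noise, then chooses the
aggressive action A or the submissive action S.  If both choose A the round
is a fight (an "AA round"): the winner is decided by a logistic contest
function of effective fighting ability, and the loser accumulates one unit
of damage.  If exactly one plays A, that individual "wins" the round without
a fight.  Choices are driven by an actor-critic learning mechanism:

* the actor is a preference logit for A, mixing an opponent-specific
  component and a generalized component with weight ``f`` (generalization is
  what produces winner-loser effects);
* the critic estimates the value of a round the same way;
* both are updated from the temporal-difference error
  ``delta = reward - estimated value``, the actor with the policy-gradient
  factor ``(chose_A - P(A))``.

Perceived rewards are +v for a round winner, -(1 + noise) for a fight loser
and 0 for playing S.  Bystanders to a fight update vicariously toward both
contestants (loser-role toward the winner, winner-role toward the loser)
with their learning rates scaled by the bystander trait ``beta``.

Everything is vectorized across groups: arrays are indexed ``[group,
individual]`` and, for opponent-specific state, ``[group, self, opponent]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from ._kernel import contest_kernel
from .genetics import LOCUS, Individual
from .params import Parameters

__all__ = [
    "LearningArrays", "ContestLog", "RoundOutcome",
    "effective_ability", "observe_relative_quality", "action_probability",
    "estimated_value", "resolve_fight", "perceived_rewards", "learning_deltas",
    "init_learning", "apply_learning_update", "bystander_update",
    "run_contest_phase", "run_group_contests",
    "davids_scores", "assign_dominance_positions",
]

_BYSTANDER_TRAITS = ("f", "alpha_theta", "alpha_w", "beta", "gamma0", "g0", "v")


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class LearningArrays:
    """Actor-critic state for all competing individuals of a batch of groups.

    ``theta_spec[g, i, j]`` / ``w_spec[g, i, j]`` are i's opponent-specific
    preference logit / value estimate for groupmate j (diagonal unused);
    ``theta_gen[g, i]`` / ``w_gen[g, i]`` are the generalized components.
    """

    theta_spec: np.ndarray
    w_spec: np.ndarray
    theta_gen: np.ndarray
    w_gen: np.ndarray

    def copy(self) -> "LearningArrays":
        return LearningArrays(self.theta_spec.copy(), self.w_spec.copy(),
                              self.theta_gen.copy(), self.w_gen.copy())


@dataclass
class ContestLog:
    """Bookkeeping of one contest phase for a batch of groups.

    ``encounters``, ``aa`` and ``wins`` are per ordered pair ``[g, i, j]``
    (``aa`` and ``encounters`` symmetric, ``wins[g, i, j]`` counts i's wins
    over j); ``damage`` and ``aa_rounds`` are per individual.  A "win" is an
    AA-fight win or being the lone A-player of a round.
    """

    encounters: np.ndarray
    aa: np.ndarray
    wins: np.ndarray
    damage: np.ndarray
    aa_rounds: np.ndarray

    @property
    def total_aa(self) -> float:
        """Total number of AA (fighting) rounds, summed over groups."""
        return float(self.aa.sum()) / 2.0


@dataclass(frozen=True)
class RoundOutcome:
    """Resolved actions of one pairwise round (scalar form, for fixtures)."""

    action_i: str                 # "A" | "S"
    action_j: str
    winner: Optional[str] = None  # "i" | "j" | None (None only for S vs S)

    def __post_init__(self):
        if self.action_i not in ("A", "S") or self.action_j not in ("A", "S"):
            raise ValueError("actions must be 'A' or 'S'")
        if self.fight and self.winner not in ("i", "j"):
            raise ValueError("an AA round must have a winner")
        if self.action_i == "A" and self.action_j == "S" and self.winner != "i":
            raise ValueError("lone A-player i is the winner")
        if self.action_j == "A" and self.action_i == "S" and self.winner != "j":
            raise ValueError("lone A-player j is the winner")
        if self.action_i == "S" and self.action_j == "S" and self.winner is not None:
            raise ValueError("an SS round has no winner")

    @property
    def fight(self) -> bool:
        return self.action_i == "A" and self.action_j == "A"


# ---------------------------------------------------------------------------
# elementary operations (numpy-broadcasting friendly)
# ---------------------------------------------------------------------------

def effective_ability(q, damage, p: Parameters):
    """Effective fighting ability: quality minus c0 per unit accumulated damage."""
    return q - p.c0 * damage


def observe_relative_quality(qi, qj, di, dj, p: Parameters, rng: np.random.Generator):
    """Noisy private observation of relative fighting ability.

    xi = a0 * (q~_i - q~_j) + N(0, sigma_obs^2), with q~ the effective
    ability; fresh noise every observation.  At the standard a0 = 0.707,
    sigma_q = sigma_obs = 0.5 the true-ability signal carries 50% of the
    observation variance over random pairs.
    """
    diff = effective_ability(qi, di, p) - effective_ability(qj, dj, p)
    if p.sigma_obs > 0:
        noise = rng.normal(0.0, p.sigma_obs, size=np.shape(diff) or None)
        if np.shape(diff) == ():
            noise = float(noise)
    else:
        noise = 0.0
    return p.a0 * diff + noise


def action_probability(theta_eff, gamma0, xi):
    """P(choose A) = logistic(theta_eff + gamma0 * xi)."""
    return expit(theta_eff + gamma0 * xi)


def estimated_value(w_eff, g0, xi):
    """Critic's estimate of the value of the coming round."""
    return w_eff + g0 * xi


def resolve_fight(qe_i, qe_j, p: Parameters, rng: np.random.Generator):
    """AA round outcome: True where i wins.

    P(i wins) = logistic(winprob_scale * (q~_i - q~_j)); the loser takes one
    unit of damage (applied by the caller).
    """
    diff = np.asarray(qe_i) - np.asarray(qe_j)
    u = rng.random(size=diff.shape or None)
    result = u < expit(p.winprob_scale * diff)
    return bool(result) if diff.shape == () else result


def perceived_rewards(outcome: RoundOutcome, traits_i, traits_j, p: Parameters,
                      rng: np.random.Generator) -> Tuple[float, float]:
    """Perceived rewards (r_i, r_j) of a resolved round.

    The round winner perceives +v (its own trait); an AA loser perceives
    -(1 + eps), eps ~ N(0, sigma_p^2); an S-player perceives 0.
    """
    def penalty() -> float:
        eps = float(rng.normal(0.0, p.sigma_p)) if p.sigma_p > 0 else 0.0
        return -(1.0 + eps)

    r_i = r_j = 0.0
    if outcome.winner == "i":
        r_i = traits_i.v
        if outcome.fight:
            r_j = penalty()
    elif outcome.winner == "j":
        r_j = traits_j.v
        if outcome.fight:
            r_i = penalty()
    return r_i, r_j


def learning_deltas(delta, chose_A, pA, alpha_theta, alpha_w):
    """Actor-critic increments from a TD error.

    Returns (d_theta, d_w): the critic moves by alpha_w * delta, the actor by
    the policy-gradient step alpha_theta * delta * (chose_A - P(A)).
    """
    d_w = alpha_w * delta
    d_theta = alpha_theta * delta * (np.asarray(chose_A, dtype=float) - pA)
    return d_theta, d_w


def init_learning(traits: np.ndarray, p: Parameters) -> LearningArrays:
    """Fresh learning state from competing-sex traits of shape (G, S, n_loci).

    Opponent-specific entries start at theta0 / w0; generalized components
    start at 0 (so the initial effective logit is (1-f)*theta0), unless
    ``init_generalized_from_traits`` puts theta0 / w0 there as well.
    """
    G, S = traits.shape[:2]
    theta0 = traits[..., LOCUS["theta0"]]
    w0 = traits[..., LOCUS["w0"]]
    theta_spec = np.repeat(theta0[:, :, None], S, axis=2)
    w_spec = np.repeat(w0[:, :, None], S, axis=2)
    if p.init_generalized_from_traits:
        theta_gen, w_gen = theta0.copy(), w0.copy()
    else:
        theta_gen = np.zeros((G, S))
        w_gen = np.zeros((G, S))
    return LearningArrays(theta_spec, w_spec, theta_gen, w_gen)


def apply_learning_update(state: LearningArrays, g: int, i: int, j: int,
                          chose_A: bool, pA: float, reward: float, w_hat: float,
                          traits_i) -> None:
    """In-place actor-critic update of individual (g, i) after a round with j.

    The increments are split between the opponent-specific entries (weight
    1-f) and the generalized components (weight f); delta = reward - w_hat.
    A zero TD error leaves the state unchanged (fixed point).
    """
    delta = reward - w_hat
    d_theta, d_w = learning_deltas(delta, chose_A, pA, traits_i.alpha_theta, traits_i.alpha_w)
    f = traits_i.f
    state.theta_spec[g, i, j] += (1.0 - f) * d_theta
    state.theta_gen[g, i] += f * d_theta
    state.w_spec[g, i, j] += (1.0 - f) * d_w
    state.w_gen[g, i] += f * d_w


def _vicarious_update(state: LearningArrays, groups: np.ndarray,
                      members_mask: np.ndarray, target: np.ndarray, reward,
                      qe: np.ndarray, tcols: dict,
                      p: Parameters, rng: np.random.Generator) -> None:
    """Bystander update of masked members toward ``target``, vectorized.

    ``groups`` (F,) indexes groups with a fight this step; ``target`` (F,) is
    the contestant (winner or loser) being learned about; ``reward`` is the
    vicarious reward, broadcastable to (F, S) (-1 for the loser role toward
    the winner, the bystander's own v for the winner role toward the loser);
    ``members_mask`` (F, S) selects bystanders.  Each bystander draws its own
    fresh observation of itself versus the target and applies the ordinary
    actor-critic update (chose_A = True) with both learning rates multiplied
    by its bystander trait beta.  ``tcols`` maps trait name -> (G, S) array.
    """
    F, S = members_mask.shape
    rows = np.arange(S)[None, :]
    gcol = groups[:, None]
    tcol = target[:, None]
    qe_g = qe[groups]                                   # (F, S)
    noise = rng.normal(0.0, p.sigma_obs, size=(F, S)) if p.sigma_obs > 0 else 0.0
    xi = p.a0 * (qe_g - qe_g[np.arange(F), target][:, None]) + noise
    f_g = tcols["f"][groups]
    th_eff = (1.0 - f_g) * state.theta_spec[gcol, rows, tcol] + f_g * state.theta_gen[groups]
    pA = action_probability(th_eff, tcols["gamma0"][groups], xi)
    w_eff = (1.0 - f_g) * state.w_spec[gcol, rows, tcol] + f_g * state.w_gen[groups]
    w_hat = estimated_value(w_eff, tcols["g0"][groups], xi)
    delta = reward - w_hat
    rate = tcols["beta"][groups]
    d_theta, d_w = learning_deltas(delta, 1.0, pA,
                                   rate * tcols["alpha_theta"][groups],
                                   rate * tcols["alpha_w"][groups])
    d_theta = np.where(members_mask, d_theta, 0.0)
    d_w = np.where(members_mask, d_w, 0.0)
    state.theta_spec[gcol, rows, tcol] += (1.0 - f_g) * d_theta
    state.theta_gen[groups] += f_g * d_theta
    state.w_spec[gcol, rows, tcol] += (1.0 - f_g) * d_w
    state.w_gen[groups] += f_g * d_w


def bystander_update(state: LearningArrays, g: int, k: int, winner: int, loser: int,
                     qe: np.ndarray, traits: np.ndarray,
                     p: Parameters, rng: np.random.Generator) -> None:
    """Single-bystander form: k (not a contestant) observed an AA round in group g.

    k applies the loser-role update (reward -1) toward the winner and the
    winner-role update (reward +v_k) toward the loser, with learning rates
    scaled by beta_k.  Bystander updates never change anyone's damage.
    ``qe`` and ``traits`` are the batch arrays (G, S) and (G, S, n_loci).
    """
    if k in (winner, loser):
        raise ValueError("a bystander cannot be a contestant")
    groups = np.array([g])
    mask = np.zeros((1, state.theta_spec.shape[1]), dtype=bool)
    mask[0, k] = True
    tcols = {n: traits[..., LOCUS[n]] for n in _BYSTANDER_TRAITS}
    _vicarious_update(state, groups, mask, np.array([winner]), -1.0,
                      qe, tcols, p, rng)
    _vicarious_update(state, groups, mask, np.array([loser]), tcols["v"][groups],
                      qe, tcols, p, rng)


# ---------------------------------------------------------------------------
# the contest phase
# ---------------------------------------------------------------------------

def run_contest_phase(q: np.ndarray, traits: np.ndarray, p: Parameters,
                      rng: np.random.Generator) -> Tuple[ContestLog, LearningArrays]:
    """Run the full contest phase for a batch of groups.

    Parameters
    ----------
    q : (G, S) individual qualities of the competing sex.
    traits : (G, S, n_loci) expressed traits in canonical order.
    p, rng : model parameters and the replicate's random stream.

    Every step, one unordered pair is drawn uniformly at random in each
    group; both members observe, choose, the round is resolved and rewards
    delivered; participants update; on AA rounds the remaining group members
    apply bystander updates.  Total accumulated damage equals the total
    number of AA rounds exactly (each fight damages exactly one individual
    by one unit).
    """
    G, S = q.shape
    if S < 2:
        raise ValueError("a group needs at least 2 competing members")

    tc = {n: np.ascontiguousarray(traits[..., LOCUS[n]], dtype=float) for n in
          ("f", "alpha_theta", "alpha_w", "beta", "gamma0", "g0", "v")}

    state = init_learning(traits, p)
    log = ContestLog(
        encounters=np.zeros((G, S, S), dtype=np.int64),
        aa=np.zeros((G, S, S), dtype=np.int64),
        wins=np.zeros((G, S, S), dtype=np.int64),
        damage=np.zeros((G, S), dtype=float),
        aa_rounds=np.zeros((G, S), dtype=np.int64),
    )
    if p.rounds_per_generation == 0:
        return log, state

    kernel_seed = int(rng.integers(1, 2 ** 31 - 1))
    contest_kernel(
        np.ascontiguousarray(q, dtype=float),
        tc["f"], tc["alpha_theta"], tc["alpha_w"], tc["beta"],
        tc["gamma0"], tc["g0"], tc["v"],
        state.theta_spec, state.w_spec, state.theta_gen, state.w_gen,
        log.encounters, log.aa, log.wins, log.aa_rounds, log.damage,
        p.rounds_per_generation, p.a0, p.sigma_obs, p.sigma_p,
        p.c0, p.winprob_scale, kernel_seed,
    )
    return log, state


def run_group_contests(group: Sequence[Individual], p: Parameters,
                       rng: np.random.Generator) -> Tuple[ContestLog, LearningArrays]:
    """Contest phase for one explicit group of :class:`Individual` objects.

    Thin wrapper over :func:`run_contest_phase` with a batch of one group
    (all returned arrays have a leading group axis of length 1).  Members'
    ``damage`` attributes are updated in place from the log.
    """
    members = [m for m in group if m.sex == "competing"]
    if len(members) < 2:
        raise ValueError("a group needs at least 2 competing-sex members")
    q = np.array([[m.q for m in members]])
    traits = np.array([[m.traits.as_array() for m in members]])
    log, state = run_contest_phase(q, traits, p, rng)
    for idx, m in enumerate(members):
        m.damage += float(log.damage[0, idx])
    return log, state


# ---------------------------------------------------------------------------
# dominance ranks
# ---------------------------------------------------------------------------

def davids_scores(wins: np.ndarray) -> np.ndarray:
    """David's scores from ordered win counts, shape (..., S, S).

    The dyadic win proportion P[i, j] is i's wins over j divided by the
    pair's decided rounds; pairs with no decided rounds contribute 1/2.
    DS = w + w2 - l - l2 with w = row sums of P, w2 = P w, l = column sums,
    l2 = P' l.
    """
    wins = np.asarray(wins, dtype=float)
    S = wins.shape[-1]
    decided = wins + np.swapaxes(wins, -1, -2)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(decided > 0, wins / np.where(decided > 0, decided, 1.0), 0.5)
    idx = np.arange(S)
    P[..., idx, idx] = 0.0
    w = P.sum(axis=-1)
    l = P.sum(axis=-2)
    w2 = np.einsum("...ij,...j->...i", P, w)
    l2 = np.einsum("...ji,...j->...i", P, l)
    return w + w2 - l - l2


def assign_dominance_positions(log: ContestLog, rng: np.random.Generator) -> np.ndarray:
    """Dominance positions (1 = top) from a contest log, shape (G, S).

    Individuals are ranked by descending David's score; exact ties are
    broken uniformly at random.  Ranks are assigned before mortality; after
    mortality, survivors keep their relative order.
    """
    scores = davids_scores(log.wins)
    tiebreak = rng.random(scores.shape)
    order = np.lexsort((tiebreak, -scores), axis=-1)
    ranks = np.empty_like(order)
    S = scores.shape[-1]
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(1, S + 1), scores.shape), axis=-1)
    return ranks
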