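"""Diploid genetics of the ten evolving traits.

Each trait is controlled by one unlinked diploid locus with additive,
real-valued alleles: the raw trait is the *sum* of the two allelic values.
Alleles roam freely over the reals; biological range constraints are applied
at expression (interference strength and the learning rates are clamped to
be nonnegative, the generalization degree to [0, 1]).  Mutation adds a
zero-mean normal increment, with a per-locus step size, to each allele
independently with probability ``mutation_rate``.

Two representations coexist:

* scalar objects (:class:`Genotype`, :class:`TraitSet`, :class:`Individual`)
  for tests and small fixtures;
* struct-of-arrays (:class:`PopulationState`) for the simulation proper,
  where alleles live in ``(n_groups, size, N_LOCI, 2)`` arrays.

Both go through the same array kernels, so there is a single source of
truth for expression, mutation and inheritance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import N_LOCI, TRAIT_NAMES, Parameters

# locus indices by trait name
LOCUS = {name: i for i, name in enumerate(TRAIT_NAMES)}


# ---------------------------------------------------------------------------
# array kernels
# ---------------------------------------------------------------------------

def express_traits(alleles: np.ndarray) -> np.ndarray:
    """Express phenotypes from allele arrays of shape ``(..., N_LOCI, 2)``.

    Returns ``(..., N_LOCI)`` in canonical trait order, with clamps applied:
    kappa, alpha_theta, alpha_w, beta >= 0; f in [0, 1]; the remaining
    traits (theta0, w0, gamma0, g0, v) unclamped.
    """
    raw = alleles.sum(axis=-1)
    out = raw.copy()
    for name in ("kappa", "alpha_theta", "alpha_w", "beta"):
        i = LOCUS[name]
        out[..., i] = np.maximum(0.0, raw[..., i])
    i = LOCUS["f"]
    out[..., i] = np.clip(raw[..., i], 0.0, 1.0)
    return out


def mutate_alleles(alleles: np.ndarray, p: Parameters, rng: np.random.Generator) -> np.ndarray:
    """Return a mutated copy: each allele independently mutates with
    probability ``p.mutation_rate``; an increment is N(0, mutation_sd[locus])."""
    out = np.array(alleles, dtype=float, copy=True)
    if p.mutation_rate <= 0.0:
        return out
    hit = rng.random(out.shape) < p.mutation_rate
    steps = rng.standard_normal(out.shape) * np.asarray(p.mutation_sd)[..., :, None]
    out += np.where(hit, steps, 0.0)
    return out


def recombine(maternal: np.ndarray, paternal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian inheritance for batches of parent allele arrays.

    ``maternal`` and ``paternal`` have shape ``(n, N_LOCI, 2)``; per offspring
    and locus, one allele is sampled uniformly from each parent's pair
    (unlinked loci, free recombination).  Returns ``(n, N_LOCI, 2)``.
    """
    maternal = np.asarray(maternal, dtype=float)
    paternal = np.asarray(paternal, dtype=float)
    n = maternal.shape[0]
    rows = np.arange(n)[:, None]
    loci = np.arange(N_LOCI)[None, :]
    pick_m = rng.integers(0, 2, size=(n, N_LOCI))
    pick_p = rng.integers(0, 2, size=(n, N_LOCI))
    child = np.empty((n, N_LOCI, 2), dtype=float)
    child[:, :, 0] = maternal[rows, loci, pick_m]
    child[:, :, 1] = paternal[rows, loci, pick_p]
    return child


# ---------------------------------------------------------------------------
# scalar objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genotype:
    """Ordered allele pairs, one per locus: array of shape (N_LOCI, 2)."""

    alleles: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alleles, dtype=float)
        if a.shape != (N_LOCI, 2):
            raise ValueError(f"alleles must have shape ({N_LOCI}, 2), got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("allelic values must be finite")
        object.__setattr__(self, "alleles", a)

    @classmethod
    def monomorphic(cls, trait_values) -> "Genotype":
        """Genotype whose expression equals ``trait_values``: every allele is
        half the trait value."""
        half = np.asarray(trait_values, dtype=float) / 2.0
        return cls(np.stack([half, half], axis=-1))


@dataclass(frozen=True)
class TraitSet:
    """Expressed, clamped phenotypic traits."""

    kappa: float
    f: float
    alpha_theta: float
    alpha_w: float
    beta: float
    theta0: float
    w0: float
    gamma0: float
    g0: float
    v: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TRAIT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "TraitSet":
        arr = np.asarray(arr, dtype=float)
        return cls(**{n: float(arr[i]) for i, n in enumerate(TRAIT_NAMES)})


@dataclass
class Individual:
    """One group member: genotype, expressed traits, quality and damage."""

    id: int
    sex: str                       # "competing" | "other"
    genotype: Genotype
    traits: TraitSet = None
    q: float = 0.0                 # non-genetic quality, drawn at birth
    damage: float = 0.0            # accumulated contest damage this season
    alive: bool = True
    group: int = 0

    def __post_init__(self):
        if self.sex not in ("competing", "other"):
            raise ValueError(f"sex must be 'competing' or 'other', got {self.sex!r}")
        if self.traits is None:
            self.traits = express_phenotype(self.genotype)


def express_phenotype(g: Genotype) -> TraitSet:
    """Additive expression of one genotype (sum of allele pairs, clamped)."""
    return TraitSet.from_array(express_traits(g.alleles))


def mutate_genotype(g: Genotype, p: Parameters, rng: np.random.Generator) -> Genotype:
    return Genotype(mutate_alleles(g.alleles, p, rng))


def make_offspring(mother: Individual, father: Individual, rng: np.random.Generator) -> Genotype:
    """Mendelian offspring genotype: one allele per locus from each parent."""
    child = recombine(mother.genotype.alleles[None], father.genotype.alleles[None], rng)
    return Genotype(child[0])


# ---------------------------------------------------------------------------
# population arrays
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Struct-of-arrays population snapshot.

    Competing-sex members of group g occupy ``comp_*[g]``; the other sex
    carries and transmits all loci but never expresses contest behaviour.
    The census n_groups*(group_size+other_sex_size) is invariant across
    generations.
    """

    generation: int
    comp_alleles: np.ndarray    # (G, S, N_LOCI, 2)
    other_alleles: np.ndarray   # (G, So, N_LOCI, 2)
    comp_q: np.ndarray          # (G, S) individual qualities

    @property
    def n_groups(self) -> int:
        return self.comp_alleles.shape[0]

    @property
    def group_size(self) -> int:
        return self.comp_alleles.shape[1]

    @property
    def census(self) -> int:
        return (self.comp_alleles.shape[0] * self.comp_alleles.shape[1]
                + self.other_alleles.shape[0] * self.other_alleles.shape[1])

    def comp_traits(self) -> np.ndarray:
        """Expressed traits of the competing sex, shape (G, S, N_LOCI)."""
        return express_traits(self.comp_alleles)


def init_population(p: Parameters, rng: np.random.Generator) -> PopulationState:
    """Monomorphic founder population.

    Every allele is half the corresponding founder trait value, so founders
    express exactly ``p.founder_traits``.  Qualities are drawn N(0, sigma_q^2)
    for the competing sex; damage starts at zero.
    """
    G, S, So = p.n_groups, p.group_size, p.other_sex_size
    half = np.asarray(p.founder_traits, dtype=float) / 2.0
    locus_pair = np.stack([half, half], axis=-1)          # (N_LOCI, 2)
    comp = np.broadcast_to(locus_pair, (G, S, N_LOCI, 2)).copy()
    other = np.broadcast_to(locus_pair, (G, So, N_LOCI, 2)).copy()
    q = rng.normal(0.0, p.sigma_q, size=(G, S))
    return PopulationState(generation=0, comp_alleles=comp, other_alleles=other, comp_q=q)
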