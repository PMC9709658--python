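"""Model parameters, validation and flat key-value config files.

All constants of the dominance/interference model and all simulation
settings live in a single frozen :class:`Parameters` record.  The default
values are the model's standard parameter set; experiment variants (degree
of local competition ``lambda_local``, parenting-damage cost ``c2``, the
costly/ineffective-interference variant obtained by swapping ``b0`` and
``phi``) are expressed by overriding individual fields, either in code via
:func:`replace` or through a plain-text config file.

Config files are deliberately minimal: one ``key: value`` pair per line,
``#`` comments, vectors comma-separated.  They are bit-exact, diffable
records of an experiment.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

#: number of evolving diploid loci (one per trait)
N_LOCI = 10

#: canonical trait order used everywhere (locus index = position here)
TRAIT_NAMES = (
    "kappa",        # interference strength, >= 0
    "f",            # generalization degree, in [0, 1]
    "alpha_theta",  # preference (actor) learning rate, >= 0
    "alpha_w",      # value (critic) learning rate, >= 0
    "beta",         # bystander learning-rate multiplier, >= 0
    "theta0",       # initial preference logit for the aggressive action A
    "w0",           # initial estimated value of a round
    "gamma0",       # weight of the observation in the action preference
    "g0",           # weight of the observation in the value estimate
    "v",            # perceived reward from performing A and winning
)

# Mutational step s.d. per locus: 5% of the largest evolved magnitude the
# trait reaches across the standard competition/damage-cost regimes, floored
# at 0.01.  Increments must reflect the scale over which a trait varies, or
# the population cannot locate its evolutionary equilibrium in a feasible
# number of generations (interference, for instance, ranges from ~0 under
# global competition to ~7 under local competition).
_DEFAULT_MUTATION_SD = (0.34, 0.013, 6.74, 0.01, 0.12, 0.28, 0.01, 0.125, 0.01, 0.048)

# Monomorphic founder phenotypes (trait order above): interference and the
# learning machinery start small but non-zero so hierarchies can begin to
# form in generation 1 and selection has variation to act on via mutation.
_DEFAULT_FOUNDER_TRAITS = (0.01, 0.05, 0.5, 0.05, 0.05, 0.0, 0.0, 0.5, 0.05, 0.5)


@dataclass(frozen=True)
class Parameters:
    """Every model constant and simulation setting.

    Defaults are the standard parameter set: pure global competition
    (``lambda_local=0``), no parenting cost of damage (``c2=0``), 500 groups
    of 8 competing-sex plus 8 other-sex individuals (census 8000).
    """

    # --- competition and reproduction ---
    lambda_local: float = 0.0   #: weight of local (within-group) competition, in [0,1]
    Q: float = 0.1              #: per-offspring probability of uncontested outside-option reproduction
    sigma_q: float = 0.50       #: s.d. of non-genetic individual quality

    # --- damage costs ---
    c0: float = 0.02            #: loss of effective fighting ability per unit damage
    c1: float = 0.0004          #: slope of mortality probability in accumulated damage
    c2: float = 0.00            #: exponential decay rate of parenting ability in damage

    # --- interference curves ---
    b0: float = 0.1             #: maximal proportional self-cost of performing interference
    b1: float = 0.5             #: saturation rate of both interference curves
    phi: float = 0.95           #: maximal proportional reduction of a subordinate's AR

    # --- observations and perceived rewards ---
    a0: float = 0.707           #: weight of true relative fighting ability in observations
    sigma_obs: float = 0.50     #: s.d. of observation noise
    sigma_p: float = 0.25       #: s.d. of perceived-penalty noise for a fight loser

    # --- population structure ---
    n_groups: int = 500
    group_size: int = 8         #: competing-sex individuals per group
    other_sex_size: int = 8

    # --- contest phase plumbing ---
    rounds_per_generation: int = 600   #: pairwise interaction steps per group per generation
    baseline_decay_rho: float = 0.25   #: decay of baseline AR across dominance ranks
    winprob_scale: float = 1.0         #: steepness of the fight-outcome logistic
    group_output_local: float = 16.0   #: expected group offspring under pure local competition

    # --- genetics ---
    mutation_rate: float = 0.002
    mutation_sd: tuple = _DEFAULT_MUTATION_SD
    founder_traits: tuple = _DEFAULT_FOUNDER_TRAITS

    # --- simulation control ---
    generations: int = 5000
    replicates: int = 100
    seed: int = 0

    # --- switches ---
    init_generalized_from_traits: bool = False  #: start theta_gen/w_gen at theta0/w0 instead of 0
    outside_option_uniform: bool = False        #: uniform outside-option parents instead of parenting-weighted
    summary_window: int = 1                     #: terminal generations averaged for equilibrium trait read-out

    def replace(self, **kwargs) -> "Parameters":
        """Return a copy with the given fields overridden (validated)."""
        p = dataclasses.replace(self, **_coerce(kwargs))
        raise_on_violations(p)
        return p


def default_parameters() -> Parameters:
    """The standard parameter set (global competition, no parenting cost)."""
    return Parameters()


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(Parameters)}
_INT_FIELDS = {
    "n_groups", "group_size", "other_sex_size", "rounds_per_generation",
    "generations", "replicates", "seed", "summary_window",
}
_BOOL_FIELDS = {"init_generalized_from_traits", "outside_option_uniform"}
_TUPLE_FIELDS = {"mutation_sd", "founder_traits"}


def _parse_value(key: str, text: str):
    text = text.strip()
    if key in _BOOL_FIELDS:
        low = text.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean for {key!r}: {text!r}")
    if key in _TUPLE_FIELDS:
        return tuple(float(x) for x in text.split(","))
    if key in _INT_FIELDS:
        return int(text)
    return float(text)


def _coerce(kwargs: dict) -> dict:
    out = {}
    for k, v in kwargs.items():
        if k not in _FIELD_TYPES:
            raise KeyError(f"unknown parameter {k!r}")
        if isinstance(v, str):
            v = _parse_value(k, v)
        elif k in _TUPLE_FIELDS:
            v = tuple(float(x) for x in v)
        elif k in _INT_FIELDS:
            v = int(v)
        out[k] = v
    return out


def load_config(path: Union[str, Path]) -> Parameters:
    """Load Parameters from a flat ``key: value`` text file.

    Unspecified keys take defaults; unknown keys fail fast.  ``=`` is
    accepted as a separator alongside ``:``.
    """
    path = Path(path)
    text = path.read_text()
    overrides: dict = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in (":", "="):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key = key.strip()
        if key not in _FIELD_TYPES:
            raise KeyError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key in overrides:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        overrides[key] = _parse_value(key, value)
    p = Parameters(**overrides)
    raise_on_violations(p)
    return p


def save_config(p: Parameters, path: Union[str, Path]) -> None:
    """Write all fields as ``key: value`` lines (round-trips with load_config)."""
    lines = []
    for f in dataclasses.fields(Parameters):
        v = getattr(p, f.name)
        if f.name in _TUPLE_FIELDS:
            v = ",".join(repr(float(x)) for x in v)
        elif f.name in _BOOL_FIELDS:
            v = "true" if v else "false"
        else:
            v = repr(v)
        lines.append(f"{f.name}: {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def validate_parameters(p: Parameters) -> list:
    """Return a list of human-readable invariant violations (empty = valid)."""
    bad = []

    def prob(name):
        v = getattr(p, name)
        if not (0.0 <= v <= 1.0):
            bad.append(f"{name} must be in [0, 1], got {v}")

    def nonneg(name):
        v = getattr(p, name)
        if not (v >= 0.0) or not math.isfinite(v):
            bad.append(f"{name} must be a finite nonnegative real, got {v}")

    def pos(name, kind=float):
        v = getattr(p, name)
        if not (v > 0):
            bad.append(f"{name} must be positive, got {v}")

    for name in ("lambda_local", "Q", "b0", "phi", "mutation_rate"):
        prob(name)
    for name in ("c0", "c1", "c2", "sigma_obs", "sigma_p", "baseline_decay_rho", "sigma_q"):
        nonneg(name)
    for name in ("b1", "a0", "winprob_scale", "group_output_local"):
        pos(name)
    for name in ("n_groups", "group_size", "other_sex_size", "rounds_per_generation",
                 "generations", "replicates", "summary_window"):
        v = getattr(p, name)
        if not isinstance(v, int) or isinstance(v, bool) or v < 0:
            bad.append(f"{name} must be a nonnegative integer, got {v!r}")
    for name in ("n_groups", "group_size", "other_sex_size", "replicates", "summary_window"):
        v = getattr(p, name)
        if isinstance(v, int) and not isinstance(v, bool) and v == 0:
            bad.append(f"{name} must be a positive integer, got 0")
    if not (isinstance(p.seed, int) and not isinstance(p.seed, bool) and p.seed >= 0):
        bad.append(f"seed must be a nonnegative integer, got {p.seed!r}")
    if len(p.mutation_sd) != N_LOCI:
        bad.append(f"mutation_sd must have exactly {N_LOCI} entries (one per locus), got {len(p.mutation_sd)}")
    elif any(not (s >= 0.0 and math.isfinite(s)) for s in p.mutation_sd):
        bad.append("mutation_sd entries must be finite nonnegative reals")
    if len(p.founder_traits) != N_LOCI:
        bad.append(f"founder_traits must have exactly {N_LOCI} entries, got {len(p.founder_traits)}")
    return bad


def raise_on_violations(p: Parameters) -> None:
    violations = validate_parameters(p)
    if violations:
        raise ValueError("invalid parameters:\n  " + "\n  ".join(violations))
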