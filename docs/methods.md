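# Methods

`domhier` simulates the co-evolution of dominance behaviour and
mating/foraging interference in a metapopulation of social groups, under a
tunable mix of local (within-group, "soft") and global (population-wide,
"hard") reproductive competition.  This note documents the model as
implemented, the choices made where the design was genuinely open, and what
the shipped test problems do and do not demonstrate.

## Life cycle

Each generation has four phases, per group of `group_size` competing-sex
individuals (plus `other_sex_size` members of the other sex, who carry and
transmit all loci but do not express contest behaviour):

1. **Hierarchy formation.**  `rounds_per_generation` interaction rounds are
   scheduled per group; each round, one unordered pair is drawn uniformly.
   Both contestants privately observe relative fighting ability and choose
   the aggressive action A or the submissive action S (details below).  An
   AA round is a fight: the winner is drawn with probability
   `logistic(winprob_scale * (q~_i - q~_j))` of effective abilities
   `q~ = q - c0*d` (quality minus a per-unit-damage decrement), and the
   loser accumulates one unit of damage.  Dominance positions are assigned
   from David's scores computed on the matrix of dyadic win proportions
   (a "win" is an AA win or being the lone A-player of a round; pairs with
   no decided round contribute 1/2), ties broken uniformly at random.
2. **Mortality.**  Each individual dies with probability `min(1, c1*d)`.
   Survivors keep their relative order and occupy recompacted positions
   `1..n_survivors`.
3. **Resource acquisition.**  The survivor at position k holds baseline
   acquired resources (AR) `a(k) = exp(-rho*(k-1))`; every living
   higher-ranked member multiplies it by the retention factor
   `1 - phi*(1 - exp(-b1*kappa_m))`; performing interference costs the actor
   a factor `1 - b0*(1 - exp(-b1*kappa_k))` of its own AR, paid once;
   damage multiplies AR by the parenting factor `exp(-c2*d)`.
4. **Reproduction and dispersal.**  The census number of offspring is
   allocated multinomially.  With probability `Q` an offspring is produced
   by uncontested outside-option reproduction (parent drawn population-wide
   among survivors, weighted by parenting ability).  Otherwise a group is
   drawn with weight `lambda_local/G' + (1-lambda_local)*A_g/sum_h A_h`
   (G' = groups with survivors, A_g = group AR sum) and the parent within it
   proportionally to effective AR.  The other-sex parent is uniform within
   the chosen parent's group.  Offspring inherit one allele per locus from
   each parent (ten unlinked diploid loci, additive alleles), mutate with
   probability `mutation_rate` per allele (normal increments with per-locus
   step sizes), and disperse globally by random permutation into the groups
   of the next generation.  Fresh qualities `q ~ N(0, sigma_q^2)` are drawn.

Under pure local competition (`lambda_local = 1`) every surviving group
expects the same output regardless of how much interference destroyed its
AR, so only relative within-group AR matters; under pure global competition
(`lambda_local = 0`) absolute AR competes population-wide, so destroying a
groupmate's AR yields no benefit while the interference cost remains.

## Contest behaviour: actor-critic learning

Each competing individual carries an opponent-specific preference logit
`theta_spec[j]` and value estimate `w_spec[j]` (initialized at the genetic
traits `theta0`, `w0`) plus generalized components `theta_gen`, `w_gen`
(initialized at 0), mixed with the generalization weight `f`:

    theta_eff = (1-f)*theta_spec[j] + f*theta_gen      (and likewise w_eff)
    P(A)      = logistic(theta_eff + gamma0*xi)
    w_hat     = w_eff + g0*xi

where `xi = a0*(q~_self - q~_opp) + N(0, sigma_obs^2)` is the private, fresh
observation of relative ability.  At the standard values (`a0 = 0.707`,
`sigma_q = sigma_obs = 0.5`) half of the observation variance over random
pairs is true signal.

Perceived rewards are `+v` (a genetic trait) for the round winner,
`-(1 + eps)` with `eps ~ N(0, sigma_p^2)` for a fight loser, 0 for playing
S.  Both participants update from the temporal-difference error
`delta = reward - w_hat`: the critic moves by `alpha_w*delta`, the actor by
the policy-gradient step `alpha_theta*delta*(chose_A - P(A))`, each split
between the specific entry (weight `1-f`) and the generalized component
(weight `f`).  Generalization transfers experience to all opponents, which
is what produces winner-loser effects.  Bystanders to a fight update
vicariously toward both contestants — the loser-role update (reward -1)
toward the winner and the winner-role update (reward `+v_self`) toward the
loser, from their own fresh observations, with both learning rates
multiplied by the bystander trait `beta`.  Bystander updates never change
damage.

The ten evolving traits are: interference strength `kappa` (clamped >= 0),
generalization `f` (clamped to [0,1]), learning rates `alpha_theta`,
`alpha_w`, bystander rate `beta` (clamped >= 0), and the unclamped `theta0`,
`w0`, `gamma0`, `g0`, `v`.  Clamping happens at expression only, so alleles
roam freely and mutation stays symmetric (no boundary-sticking bias).

## Parameters

Standard values (defaults of `default_parameters()`): `lambda_local = 0`,
`Q = 0.1`, `sigma_q = 0.50`, `c0 = 0.02`, `c1 = 0.0004`, `c2 = 0` (variant
0.04), `b0 = 0.1`, `b1 = 0.5`, `phi = 0.95`, `a0 = 0.707`,
`sigma_obs = 0.50`, `sigma_p = 0.25`; 500 groups of 8 + 8 (census 8000);
mutation rate 0.002 per allele per generation; 5000 generations, 100
replicates.

Four quantities are model plumbing with no published value; they are
first-class parameters so their influence can be probed:

* `rounds_per_generation = 600` — the interaction budget per group
  (~21 encounters per pair for 28 pairs).
* `baseline_decay_rho = 0.25` — the baseline AR skew over ranks; the
  top-to-bottom baseline ratio in a full group is e^1.75 ~ 5.8.
* `winprob_scale = 1` — steepness of the fight-outcome logistic.
* `group_output_local = 16` — the expected group output under pure local
  competition.  With a conserved census this is census/n_groups
  automatically; the parameter is retained as documentation and for
  expected-RS illustrations.

**Mutational step sizes.**  Increments must reflect the scale over which a
trait varies, or the population cannot traverse to its equilibrium in a
feasible number of generations: interference ranges from ~0 under global
competition to ~7 under local competition, so a step sized to the global
regime (~0.01) would leave `kappa` effectively frozen.  Default steps are 5%
of the largest evolved magnitude each trait reaches across the standard
regimes, floored at 0.01: (0.34, 0.013, 6.74, 0.01, 0.12, 0.28, 0.01,
0.125, 0.01, 0.048) in canonical trait order.

**Founders.**  Populations start monomorphic at small, near-zero trait
values (`kappa = 0.01`, `f = 0.05`, `alpha_theta = 0.5`, `alpha_w = 0.05`,
`beta = 0.05`, `theta0 = 0`, `w0 = 0`, `gamma0 = 0.5`, `g0 = 0.05`,
`v = 0.5`), configurable via `founder_traits`.  Published equilibria do not
state initial conditions; equilibrium independence from founders should be
checked per study, not assumed.

## Randomness and reproducibility

One master seed yields one `numpy` Generator stream per replicate
(`SeedSequence(master, spawn_key=(replicate,))`), so replicate r is
reproducible without running the others.  The compiled contest kernel is
seeded once per generation with an integer drawn from the replicate stream.
Identical seeds give bit-identical trajectories.

## Scaled-down study conditions

Full-scale runs (500 groups x 5000 generations x 100 replicates) are the
published conditions; the package's shipped desk preset scales down only the
quantities that affect statistical power and equilibration time — 50 groups,
2000 generations, single-digit replicates — while keeping every behavioural
and selection parameter, including the standard 600-round contest schedule,
at its standard value.  Within-generation quantities (fighting totals,
damage, skew) are then directly comparable across regimes, at the price of
noisier trait read-outs and slower equilibration.  Equilibrium read-outs use
the final generation by default; `summary_window` averages a terminal window
to reduce noise in scaled-down runs.

At this preset the two competition regimes separate cleanly: under local
competition interference evolves to the several-unit range with
winner-take-most skew, while under global competition it stays within
mutation-selection distance of zero, with or without the parenting cost.

## Numerical choices

* Logistic evaluated in the numerically stable branch form; extreme logits
  saturate to 0/1 exactly, which is the intended behaviour.
* Quartiles use linear interpolation (`numpy.percentile` default).
* David's-score ties are broken uniformly at random; zero-encounter pairs
  are imputed a win proportion of 1/2.
* The skew index M uses the multinomial-corrected normalized sum of squared
  shares, `M = [sum s_k^2 - 1/n - (1-1/n)/O]/(1-1/n)`: ~0 in expectation for
  equal multinomial allocation, `1 - 1/O` under monopoly, NaN for fewer than
  two survivors or zero offspring.  It is isolated behind a single function
  so an alternative index can be swapped in.
* Degenerate inputs: a group whose survivors all have zero effective AR
  (possible only at `phi = 1`) allocates its contested weight uniformly
  among its survivors; population-wide extinction raises `ExtinctionError`.

## Open design points and limitations

* The interaction schedule (random pair per round, fixed budget) and the
  baseline-AR curve are conventions; evolved fighting totals scale with the
  round budget whenever aggression saturates the schedule, so comparisons of
  fighting *between regimes* are more robust than absolute totals.
* The actor update is the standard policy-gradient form; the bystander rule
  is a concrete vicarious winner/loser-role update.  Other functional forms
  could shift quantitative equilibria; directions (interference under local
  but not global competition; less fighting under parenting costs) were
  robust across the forms tried.
* No kin structure, age structure, linkage, explicit other-sex behaviour or
  between-group aggression.
* Synthetic populations draw qualities i.i.d. normal each generation; real
  populations have persistent state (age, condition carry-over) that the
  model deliberately omits, so passing tests speak to the model's internal
  logic, not to any particular field system.
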