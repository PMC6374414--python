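# Methods

## The model class

`mpdyn` works with discrete hidden Markov models whose hidden state is split
into independent *factors*.  Factor `f` has `m_f` levels, a column-stochastic
transition matrix `B` (`B[i, j] = P(s_{t+1}=i | s_t=j)`) and an initial prior
`D` (`D[i] = P(s_1=i)`).  Observations arrive through *modalities*, each with
a likelihood matrix `A` (`A[i, j] = P(o_t=i | s_t=j)`) that depends on exactly
one factor.  Because no likelihood couples factors, the posterior factorises
and every algorithm in the package runs per factor; free energies sum over
factors.  Outcomes may be marked "not yet observed", in which case their
likelihood message is the all-ones vector — ones rather than uniform, so that
products of messages remain interpretable as unnormalised joint terms.

## Three inference schemes, one dynamical form

All three schemes estimate the per-time-step posterior marginals
`Q(s_t)` and share the same neuronal parameterisation: a membrane potential
`v_t` (log-space belief), a firing rate `s_t = softmax(v_t)`, and a prediction
error `eps_t = (log-target - mean) - v_t`.  Beliefs evolve by explicit Euler
on `dv/dt = eps`, every time step and factor updated in parallel, stopping
when `max |eps| < tol`.  The schemes differ only in the log-target:

* **Variational (mean-field) message passing.**  The target is
  `ln A[o_t] + (ln B) q_{t-1} + (ln B)^T q_{t+1}` — expectations of the *log*
  transition probabilities under neighbouring beliefs.  Its fixed points are
  the stationary points of the mean-field variational free energy.
* **Marginal message passing.**  The target is
  `ln A[o_t] + a ln(B q_{t-1}) + a ln(B† q_{t+1})` — the expectation moves
  *inside* the log and is attenuated by a corrective exponent `a` (default
  1/2).  `B†` is the Bayes inversion of `B` under a flat prior (transpose
  with renormalised columns), so the backward message runs the chain in
  reverse.  Fixed points minimise the per-step marginal free energy below.
* **Belief propagation.**  The target is the sum-product update
  `ln A[o_t] + ln(B (mu_fwd[t-1] * A[o_{t-1}])) + ln(B^T (mu_bwd[t+1] * A[o_{t+1}]))`.
  The message populations are recovered from the marginals algebraically at
  each step — the adiabatic limit of message neurons with much shorter time
  constants (`msg_time_ratio` switches on an explicit fast relaxation
  instead).

### Recovering BP messages from marginals

The forward message population is `mu_fwd[t] ∝ s_t / (A[o_t] * G_t)` where
`G_t = B^T (mu_bwd[t+1] * A[o_{t+1}])` is the *incoming* message from the
future, and symmetrically for the backward population.  Dividing by the
incoming message (rather than the local backward population) matters: the
product `mu_fwd * mu_bwd` is pinned by the marginal, but the split between
the two directions is not, and a split-agnostic recovery admits a continuum
of spurious fixed points.  Anchored by the boundary terms (`D` enters the
first step's target; the last step has no future term), the recovery used
here makes the scheduled sum-product solution the unique joint fixed point;
the suite verifies agreement with an independent enumeration oracle to
KL < 1e-15 per step.  A further numerical point: `ln s` in the message
recovery is the exact log-softmax of `v`, not the floored logarithm of `s` —
beliefs sharper than the log floor must divide out exactly, otherwise the
ratio explodes and the network cannot converge on near-deterministic models.

### The overcounting lesion

`BeliefPropagation(..., overcount_lesion=True)` removes the subtraction of
the ascending likelihood message from the forward-message computation, so the
next step's marginal receives the likelihood twice (a circular-inference
lesion; only the BP circuit has this subtractive connection).  Its robust
signatures, asserted in the suite, are (i) exact no-op when the likelihood is
uninformative and (ii) systematic deviation of the converged beliefs from the
exact marginals that the intact circuit attains.  Plausible-sounding sharper
operationalisations turn out not to hold at this model scale: per-step
entropy decreases at only ~60% of observed steps, and the lesioned beliefs
are typically *farther* (in KL) from the per-step normalised likelihood,
because the doubled messages concern past outcomes propagated through `B`,
not the current one.

## Free energies

* **Variational free energy** (mean-field family): energy takes expectations
  of `ln B` under outer products of adjacent singleton beliefs plus the
  expected log likelihood; entropy is the sum of singleton entropies.
* **Bethe free energy**: the family keeps adjacent pairwise marginals; the
  energy uses true pairwise expectations and the Bethe entropy subtracts the
  neighbour mutual information.  On this acyclic chain it is exact: at the
  true posterior it equals `-ln P(o)` (verified to 1e-9).
* **Marginal free energies**: per-step functionals
  `F_F(t)` and `F_B(t)` with empirical priors `ln(B q_{t-1})` from the past
  and `ln(B† q_{t+1})` from the future; the marginal free energy `F(t)`
  mixes the two directed priors half-and-half while counting the likelihood
  and entropy once, hence `F(t) = (F_F(t) + F_B(t)) / 2` exactly.

The per-step sum `F_F + F_B` is conjectured (not proven) to upper-bound a
leave-one-out reference `-E_Q[ln P(o_t, s_t | o_{\t})] - H[Q(s_t)]`; the
package computes the exact reference by enumeration (size-guarded, no
approximate fallback) and reports the slack.  Empirically the slack is
non-negative away from the chain end but goes negative at the final step,
where `F_B` has no empirical prior term under the boundary convention used
throughout (first step's past term is the prior `D`; last step's future term
is omitted).  The sweep reports both the global and the before-final-step
minima and never clips a negative value.

## Numerical choices

* Logarithms are floored as `log(x + 1e-16)` so structural zeros
  (deterministic priors, permutation transitions) stay finite.
* Stochastic matrices are validated to a column-sum tolerance of 1e-10 and
  renormalised only within that tolerance.
* Euler step 0.1, tolerance 1e-6 on `max |eps|`, integration budget 500 time
  units; non-convergence is flagged on the trajectory, never raised.
* Gauge fixing: log-targets and potentials are mean-subtracted per time step,
  so adding a constant to any `v` changes nothing downstream; initial
  potentials are gauge-fixed on entry, which makes warm-started runs exactly
  shift-invariant.
* Forward/backward sweeps normalise messages per step; the forward
  normalisers are retained and their logs summed to give `ln P(o)`.
* Ties in MAP readouts break toward the lowest state index.
* All computations are deterministic given inputs; generators thread a single
  integer seed through `numpy.random.default_rng`.

A known limitation of the marginal scheme follows from the 1/2 exponent: for
a factor with *deterministic* transitions and no observations, the
wrong-state log-odds obey `ln w_t = (ln w_{t-1} + ln w_{t+1}) / 2`, which is
only marginally stable, so the log floor leaks (`floor^(2^-k)`) and the
last few steps retain visible tail mass.  All schemes still agree on the MAP
sequence there; exact pairwise agreement (KL < 1e-8) in the deterministic
limit is asserted for models in which every factor is observed.

## The synthetic-data generator

`fig_model` builds the demonstration model: two hidden factors of three
levels over fifteen steps, deterministic initial states, sticky stochastic
transitions (`stickiness` = self-transition mass, default 0.7, off-diagonal
mass spread evenly), and a single three-outcome modality on the first factor
with `likelihood_acuity` (default 0.8) on the matched outcome.  The second
factor is never observed, giving one factor with informative-but-uncertain
input and one with none.  The published rendition of this experiment shows
its matrices graphically rather than numerically, so these defaults are the
package's parameterisation of that regime; externally supplied matrices can
be loaded through `mpdyn.io` for exact reproduction of a particular run, and
the headline divergence numbers scale with the actual matrices used.
`random_model` draws every column of `A`, `B` and the prior from a symmetric
Dirichlet; `sample_trajectory` is ancestral sampling.

What the generator does not emulate: structural zeros in the transition
matrices (the published experiment has transitions that never occur),
asymmetric off-diagonal structure, multiple modalities per factor, and any
non-stationarity.  Passing tests therefore demonstrate the schemes'
comparative behaviour in a symmetric sticky regime, not on any particular
empirical dataset.

One operationalisation deliberately not asserted: ranking the *growth* of
the unobserved-factor entropy profiles by rank correlation with time cannot
separate the schemes, because the mean-field profile is strictly increasing
at the free chain end for any ergodic sticky `B` (Spearman rho is exactly 1
for both schemes).  The overconfidence is a *level* effect, and the suite
asserts it as such: mean and penultimate-step entropy of the mean-field
beliefs sit well below exact inference, and the mean per-step entropy
ordering VMP <= BP <= MMP holds across replicates.

## Evaluation harness

`online_experiment` presents outcomes sequentially: after each new outcome
the remaining steps are masked, each scheme warm-starts from its previous
state and integrates to convergence, and beliefs over all time steps are
snapshotted (a cold-start mode exists for fixed-point uniqueness checks).
Schemes are compared by summed KL from the BP beliefs (exact here), MAP
error counts against the generating states, per-step entropy profiles, and
an update-timing profile (cumulative L1 path length of the beliefs over
concatenated integration time) that quantifies how front-loaded belief
updating is.  `architecture_cost` returns the neuronal population counts of
the two circuit layouts: `2 n m t` for the marginal-coupled schemes (one
belief and one error population per state, factor and time step) and
`4 n m t` for belief propagation (two extra directed message populations).

Problem sizes used by the verification suites: 100 random models with 1–2
factors of 2–3 levels and horizons up to 6 for the oracle and free-energy
checks; 50 seeded replicates of the two-factor experiment for the
overconfidence comparison; 1000 random 2-state 4-step models for the
inequality sweep.
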