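# Methods

## Model

An infinite population of buyers (four strategies: Buy, Disc, AntiDisc,
NoBuy) faces an infinite population of sellers (two deterministic
strategies: ship C, defect D) in single-shot trust games.  Payoffs per game:
no purchase → (0, 0); purchase + ship → (b, b) with 0 < b < 1; purchase +
defect → (exploited, 1) with exploited < 0.  The ordering
1 > b > 0 > exploited makes the interaction a social dilemma: defection is
the seller's dominant action in the one-shot game, so without further
structure the only equilibrium is no trade.

Each seller carries a public binary reputation (G/B), instantaneously
visible to everyone, re-scored after every purchase.  A fraction q of buyers
are image scorers (G after shipping, B after defection); the rest are
indifferent scorers (always G).  Scores are flipped with assignment error
mu ∈ [0, 1/2); buyers' realized actions flip with implementation error
eps ∈ [0, 1/2), giving the buy-probability pairs (toward G and B sellers)
Buy = (1−eps, 1−eps), Disc = (1−eps, eps), AntiDisc = (eps, 1−eps),
NoBuy = (eps, eps).  Buyer–seller pairs meet at most once, so reputation is
the only channel through which a seller's past actions matter.

### Key assumptions

* **Timescale separation.** Reputations relax much faster than strategy
  frequencies, so all payoffs are evaluated at the stationary distribution
  of each seller's reputation chain.  The expected payoff so obtained is
  exact in the long-game limit regardless of initial reputations (verified
  against Cesàro averages of the transition matrix and against the
  agent-based simulator).
* **Scorer type is payoff-neutral.**  A buyer's payoff depends on its
  strategy, not on how it scores, so the image-scorer fraction q is a fixed
  parameter, and equality of the strategy mix across the two scorer classes
  is preserved by the replicator flow (a tested conservation law).
* **Sellers act deterministically; buyers are noisy.**

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `b` | cooperation payoff | 0.5 | must lie in (0, 1) |
| `exploited_payoff` | buyer's payoff when exploited | −1.0 | any negative value; −1 is the natural normalization against the defector's payoff 1 and is used throughout the examples |
| `mu` | assignment error | 0.1 | [0, 1/2) |
| `eps` | implementation error | 0.1 | [0, 1/2) |
| `q` | image-scorer fraction | 1.0 | [0, 1] |

All payoffs are dimensionless; replicator time is in units of the inverse
payoff scale.

The *reference parameter set* used for the scorer-threshold example is
b = 0.2, mu = 0.1, eps = 0.02, at which the minimal image-scorer fraction is
0.604 (reported as 0.60); at b = 0.8 with the same errors it is 0.038.

## Closed forms

With population buy probabilities P_G, P_B and M = mu + q(1−2mu):

* stationary reputations: g_C = (1−mu)P_B / ((1−mu)P_B + mu·P_G) and
  g_D = (1−M)P_B / ((1−M)P_B + M·P_G).  When the scorer classes carry
  different strategy mixes, the class-specific buy probabilities are paired
  with the class-specific error rates in g_D.
* cooperative equilibrium: seller indifference fixes
  P_B/P_G = (bM − mu)/((1−mu) − b(1−M)), hence the Buy share
  x_Buy = (P_B − eps)/(1−2eps); buyer indifference between Buy and Disc
  fixes z = c(1−g_D)/(c(1−g_D) + b(1−g_C)) with c = −exploited_payoff.
  Existence requires b(eps + M(1−2eps)) > eps + mu(1−2eps); note the
  condition does not involve the exploited payoff, which only shifts z.
* degenerate case: if nobody ever buys (possible only with eps = 0), the
  reputation chain never moves and the stationary distribution is not
  unique; the closed forms return g = 1/2, the frozen initial population
  average used by the verification iteration.  Payoffs are unaffected (they
  are zero in every such reachable state).

## Numerical choices

* **Reputation fixed-point verification**: iterate the one-step averaged
  update from g = 0.5, tolerance 1e−12, cap 1e6 iterations (the map is a
  contraction for valid inputs; the cap guards pathological calls).
* **Nash tolerance**: a state is approximately Nash when no unilateral
  deviation gains more than 1e−6 (payoffs are floating point).  The
  brute-force catalogue check uses a 0.1-step simplex grid × 0.05-step z
  grid and accepts hits within Euclidean distance 0.15 of a reported
  equilibrium (grid resolution).  It samples eps ≥ 0.02: with eps = 0 the
  no-trade corner supports a continuum of payoff-ties (nobody transacts and
  z is payoff-neutral), so noise is what makes the catalogue generic.
* **Threshold bisection**: bracket width 1e−10 on q ∈ [0, 1]; monotonicity
  of the existence margin in q is asserted on a 21-point pre-scan before
  bisecting.
* **Jacobian**: the reduced (Buy/Disc-face, seller) system is differentiated
  symbolically (sympy, cached lambdify) and cross-checked entrywise against
  central differences (step 1e−6) of the independently hand-coded numeric
  vector field.  The (z, z) entry is exactly zero because the seller payoff
  difference is z-free; stability is trace < 0 and det > 0.
* **Singular equilibrium detection**: exact-equality test on the existence
  margin with tolerance 1e−12; generic parameters return none.
* **Orbit classification**: an orbit is classified when it comes within
  delta = 1e−3 (Euclidean, full state) of an equilibrium; unclassified
  orbits have their horizon doubled from 1e4 up to 1e6 time units and are
  then reported `undecided`.  Single orbits use adaptive RK45
  (`solve_ivp`, rtol 1e−8/atol 1e−10) with terminal proximity events.
* **Basin volumes** advance all Monte-Carlo samples together through one
  adaptive RK45 solver on the stacked system (rtol 1e−6/atol 1e−9),
  retiring classified orbits at checkpoints whose spacing doubles from 25
  time units; this is what makes 2000-sample sweeps cheap on one CPU.  The
  same classification rule as above applies.  Initial mixtures are
  symmetric-Dirichlet(1) draws on the 3-simplex (Buy, Disc, NoBuy) or
  4-simplex, z uniform; the 95% interval is the Wilson score interval.
* **Boundary handling**: replicator boundaries are invariant, so
  frequencies are clipped at 0 only below 1e−15 and clipped states are
  logged at debug level; simplex sums are renormalized when drift exceeds
  1e−12.

## Agent-based validator

Finite populations: every round each seller is matched with an
independently, uniformly drawn buyer (with replacement — the
infinite-population no-repeat-pairs limit), reputations are public and
updated instantly, and the seller's initial reputations are random (the
long-run results are initial-condition independent, which is tested).
Accounting is per game: buyer payoffs per game participated, seller payoffs
per game played.  Standard errors use batch means (20–40 batches) over
post-burn-in rounds, which absorbs the autocorrelation induced by
reputation persistence; burn-in defaults to 10% of rounds.  The stochastic
validation suite uses 20 random parameter/state points at 1e4 seller-rounds
each (10 sellers × 1000 post-burn-in rounds, 40 buyers), drawing mu, eps ≥
0.05 and well-mixed strategy compositions so that reputation chains mix on
a scale of ~10 rounds — several times shorter than a 50-round batch; the
finite composition is constructed first and the analytic comparison uses
the exactly realized frequencies, making the closed forms unbiased
predictions of the finite simulation.

## What the generator emulates — and what it does not

Synthetic conditions (random parameter draws, uniform initial states,
mixed compositions) cover the model's full valid parameter region.  They do
not emulate real marketplace features outside the model: buyer reputations,
repeated buyer–seller pairs, private or delayed reputation information,
more than two reputation states, or evolution of the scorer fraction q.
Passing tests therefore certify the internal mathematics and its stochastic
realization, not the fidelity of the model to any particular marketplace.

## Known limitations

* Finite-precision replicator orbits can drive a strategy frequency to
  exactly zero (underflow) while the true orbit merely comes close; the
  orbit is then trapped on that boundary face and may settle on a boundary
  fixed point (e.g. pure Disc with all-C sellers) that the exact flow would
  leave.  Such orbits are reported `undecided` rather than misclassified;
  at default tolerances this affects well under 1% of basin samples.
* The singular equilibrium is a measure-zero knife edge; it is detected
  only under exact (1e−12) parameter equality, by design.
* The ABM validates payoffs and reputations; it deliberately contains no
  selection dynamics (the replicator module is the selection model).
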