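# trustgame

Evolutionary analysis of the asymmetric **trust game with a seller-side
reputation mechanism** — the stylized model of an online marketplace in which
unacquainted buyers and sellers nevertheless manage to cooperate.

A buyer (investor) first decides whether to buy.  No purchase gives both
players 0.  On a purchase, a shipping seller (C) gives both players `b`
(`0 < b < 1`), while a defecting seller (D) keeps the goods: the seller earns
the temptation payoff 1 and the buyer the negative exploited payoff.  Each
seller carries a public binary reputation, good (G) or bad (B), re-scored by
the buyer after every purchase.  **Image scorers** (a fraction `q` of buyers)
score the seller's action — G after shipping, B after exploiting — while
**indifferent scorers** (`1 − q`) always report G.  Scores are flipped with
assignment-error probability `μ`, and the buyer's realized action deviates
from the intended one with implementation-error probability `ε`.  Buyers play
one of four strategies: `Buy`, `Disc` (buy from G only), `AntiDisc` (buy from
B only), `NoBuy`.

The package is for researchers in evolutionary game theory and the economics
of reputation systems who want a complete, tested implementation of this
model: exact formulas, equilibria, dynamics, and a stochastic cross-check.

## What it computes

* **Reputation calculus** — each seller's reputation is a two-state Markov
  chain; with population buy probabilities `P_G`, `P_B` the stationary
  good-standing probabilities are

  `g_C = (1−μ) P_B / ((1−μ) P_B + μ P_G)`,
  `g_D = (1−M) P_B / ((1−M) P_B + M P_G)`,  where `M = μ + q (1−2μ)`

  is the chance a defector gets scored B.  `g_C` ignores `q`; `g_D` falls as
  image scorers become more common.
* **Closed-form expected payoffs** (long-run, any initial reputation) for all
  four buyer strategies and both seller types, validated against the Markov
  chain's Cesàro averages and an agent-based simulator.
* **Nash equilibria** — the always-present strict *uncooperative* equilibrium
  (`NoBuy`, all-D); the *cooperative* Buy/Disc mixture with a high C-seller
  fraction, which exists iff `b (ε + M(1−2ε)) > ε + μ(1−2ε)` and is then
  asymptotically stable; and a knife-edge *singular* line.  A brute-force
  approximate-Nash search over a discretized state space verifies the
  catalogue is exhaustive.
* **Two-population replicator dynamics** — integration, attractor
  classification, and Monte-Carlo measurement of the cooperative basin of
  attraction.
* **Agent-based model** — finite populations playing the noisy game with
  public reputations; empirical payoffs converge to the closed forms at the
  Monte-Carlo rate.

## Worked example

```python
import trustgame as tg

params = tg.GameParams(b=0.5, mu=0.1, eps=0.1, q=1.0)

coop = tg.cooperative_equilibrium(params)
print(coop.buyer_mix)          # [0.3382 0.6618 0.     0.    ]
print(coop.z)                  # 0.9
print(coop.stability)          # asymptotically_stable

prof = tg.expected_payoffs(params, coop.state())
print(prof.buyer)              # [0.315 0.315 0.035 0.035]
print(prof.seller_C, prof.seller_D)          # 0.39375 0.39375
print(prof.reputation.g_C, prof.reputation.g_D)  # 0.7875  0.04375

est = tg.basin_volume(params, n_samples=2000, seed=1234, restrict=3)
print(est.volume)              # 0.9225
```

Read: in the cooperative equilibrium 34% of buyers buy unconditionally and
66% discriminate; 90% of sellers ship.  Buy and Disc are exactly indifferent
(0.315 each) and strictly beat AntiDisc/NoBuy (0.035); C and D sellers are
indifferent (0.39375) — the defining property of the mixed equilibrium.
Shipping sellers hold a good reputation 78.75% of the time, defectors only
4.375%.  From uniform random initial conditions (AntiDisc excluded), 92% of
states evolve to this cooperative equilibrium rather than to market collapse.

The threshold fraction of image scorers needed for cooperation to be
sustainable at all:

```python
tg.image_scorer_threshold(tg.GameParams(b=0.2, mu=0.1, eps=0.02))  # 0.6042
tg.image_scorer_threshold(tg.GameParams(b=0.8, mu=0.1, eps=0.02))  # 0.0378
```

— a strong dilemma (`b = 0.2`) needs 60% image scorers, a weak one
(`b = 0.8`) under 4%.

There is also a CLI with the same functionality:

```bash
trustgame --config cfg.yaml equilibria
trustgame --config cfg.yaml threshold --solve-for q
trustgame --config cfg.yaml scan --x-param b --x-range 0.1:0.9:41 --y-param q --y-range 0:1:41
trustgame --config cfg.yaml phase --x0 0.3,0.6,0.0,0.1 --z0 0.8
trustgame --config cfg.yaml --seed 7 basin --samples 2000 --strategies 3
trustgame --config cfg.yaml --seed 7 abm --rounds 1000
```

where `cfg.yaml` is a flat key-value file (`b`, `exploited_payoff`, `mu`,
`eps`, `q`, plus numerics such as `n_samples` or `rounds`).

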