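"""Stochastic agent-based simulator of the trust game with public reputations.

Finite populations of buyers and sellers play the single-shot trust game:
every round each seller is matched with an independently, uniformly drawn
buyer (buyers may serve several sellers per round, mimicking the
infinite-population no-repeat-pairs limit).  The buyer buys with its
strategy's probability given the seller's current public reputation; on a
purchase the seller acts deterministically (C ships, D exploits), payoffs
accrue, and the buyer re-scores the seller according to its scorer type with
assignment error ``mu``.  No purchase leaves the reputation untouched.

The simulator is the stochastic validator of the closed-form payoff
calculus: post-burn-in empirical payoff means and good-reputation
occupancies converge to the analytic values with Monte-Carlo error.
Standard errors are computed by batch means over rounds, which is robust to
the autocorrelation the persistent reputations induce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GameParams, PopulationState, strategy_profile

__all__ = ["ABMConfig", "ABMResult", "run_abm", "reputation_timeseries"]

_N_BATCHES = 40


@dataclass(frozen=True)
class ABMConfig:
    """Composition and schedule of one agent-based run.

    ``buyer_counts`` is a 4x2 integer array: rows follow the strategy order
    (Buy, Disc, AntiDisc, NoBuy), columns are (indifferent scorers, image
    scorers).  ``n_c_sellers`` of the ``n_sellers`` sellers ship.
    """

    params: GameParams
    buyer_counts: np.ndarray
    n_sellers: int
    n_c_sellers: int
    rounds: int
    burn_in: int
    seed: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.buyer_counts, dtype=int)
        if counts.shape != (4, 2) or np.any(counts < 0):
            raise ValueError("buyer_counts must be a non-negative 4x2 integer array")
        object.__setattr__(self, "buyer_counts", counts)
        if counts.sum() < 1:
            raise ValueError("at least one buyer is required")
        if not 0 <= self.n_c_sellers <= self.n_sellers or self.n_sellers < 1:
            raise ValueError(
                f"need 0 <= n_c_sellers ({self.n_c_sellers}) <= n_sellers "
                f"({self.n_sellers}) and n_sellers >= 1"
            )
        if not 0 <= self.burn_in < self.rounds:
            raise ValueError("need rounds > burn_in >= 0")

    @property
    def n_buyers(self) -> int:
        return int(np.asarray(self.buyer_counts).sum())

    @classmethod
    def from_state(
        cls,
        params: GameParams,
        state: PopulationState,
        n_buyers: int,
        n_sellers: int,
        rounds: int,
        burn_in: int | None = None,
        seed: int = 0,
    ) -> "ABMConfig":
        """Discretize a population state into agent counts (largest remainder)."""
        weights = np.stack(
            [state.x * (1.0 - params.q), state.y * params.q], axis=1
        )  # (4, 2)
        ideal = weights / weights.sum() * n_buyers
        counts = np.floor(ideal).astype(int)
        short = n_buyers - counts.sum()
        if short:
            order = np.argsort((ideal - counts).ravel())[::-1][:short]
            counts.ravel()[order] += 1
        n_c = int(round(state.z * n_sellers))
        if burn_in is None:
            burn_in = rounds // 10
        return cls(
            params=params,
            buyer_counts=counts,
            n_sellers=n_sellers,
            n_c_sellers=n_c,
            rounds=rounds,
            burn_in=burn_in,
            seed=seed,
        )


@dataclass(frozen=True)
class ABMResult:
    """Empirical per-game payoffs and reputation occupancies with SEs.

    Buyer payoffs are averaged per game participated (strategies absent from
    the composition report NaN); seller payoffs per game played.  ``g_C`` and
    ``g_D`` are time-averaged fractions of good reputation among C and D
    sellers.  All standard errors come from post-burn-in batch means.
    """

    buyer_payoff: np.ndarray
    buyer_payoff_se: np.ndarray
    buyer_games: np.ndarray
    seller_C_payoff: float
    seller_C_payoff_se: float
    seller_D_payoff: float
    seller_D_payoff_se: float
    g_C: float
    g_C_se: float
    g_D: float
    g_D_se: float
    rounds_used: int
    seed: int


def _batch_se(per_batch_sum: np.ndarray, per_batch_n: np.ndarray):
    """Mean and batch-means SE from per-batch sums/counts (NaN when absent)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        total_n = per_batch_n.sum(axis=0)
        mean = per_batch_sum.sum(axis=0) / total_n
        bm = per_batch_sum / per_batch_n  # per-batch means
    k = np.sum(per_batch_n > 0, axis=0)
    bm_mean = np.where(per_batch_n > 0, bm, 0.0).sum(axis=0) / np.maximum(k, 1)
    dev = np.where(per_batch_n > 0, (bm - bm_mean) ** 2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(dev.sum(axis=0) / np.maximum(k - 1, 1) / np.maximum(k, 1))
    se = np.where(k > 1, se, np.nan)
    return mean, se


def _simulate(config: ABMConfig, record_timeseries: bool):
    params = config.params
    rng = np.random.default_rng(config.seed)
    counts = np.asarray(config.buyer_counts)
    strat = np.repeat(np.arange(4), counts.sum(axis=1))
    is_image = np.concatenate(
        [np.repeat([False, True], counts[s]) for s in range(4)]
    )
    n_buyers, n_sellers = strat.size, config.n_sellers
    is_C = np.zeros(n_sellers, dtype=bool)
    is_C[: config.n_c_sellers] = True
    rep_G = rng.random(n_sellers) < 0.5  # initial reputations irrelevant in the long run
    p = strategy_profile(params.eps)

    n_post = config.rounds - config.burn_in
    n_batches = min(_N_BATCHES, n_post)
    batch_of = np.minimum(
        np.arange(n_post) * n_batches // n_post, n_batches - 1
    )
    pay_sum = np.zeros((n_batches, 4))
    pay_sq = np.zeros((n_batches, 4))
    pay_n = np.zeros((n_batches, 4))
    sell_sum = np.zeros((n_batches, 2))  # columns: C, D
    sell_n = np.zeros((n_batches, 2))
    occ_sum = np.zeros((n_batches, 2))  # per-round G fractions among C, D
    occ_n = np.zeros((n_batches, 2))
    ts = np.full((config.rounds, 2), np.nan) if record_timeseries else None

    b, exploited = params.b, params.exploited_payoff
    for r in range(config.rounds):
        buyers = rng.integers(0, n_buyers, size=n_sellers)
        s = strat[buyers]
        pbuy = p[s, np.where(rep_G, 0, 1)]
        buys = rng.random(n_sellers) < pbuy
        if record_timeseries:
            ts[r, 0] = rep_G[is_C].mean() if is_C.any() else np.nan
            ts[r, 1] = rep_G[~is_C].mean() if (~is_C).any() else np.nan
        if r >= config.burn_in:
            k = batch_of[r - config.burn_in]
            buyer_pay = np.where(buys, np.where(is_C, b, exploited), 0.0)
            pay_sum[k] += np.bincount(s, weights=buyer_pay, minlength=4)
            pay_sq[k] += np.bincount(s, weights=buyer_pay**2, minlength=4)
            pay_n[k] += np.bincount(s, minlength=4)
            seller_pay = np.where(buys, np.where(is_C, b, 1.0), 0.0)
            sell_sum[k, 0] += seller_pay[is_C].sum()
            sell_sum[k, 1] += seller_pay[~is_C].sum()
            sell_n[k, 0] += is_C.sum()
            sell_n[k, 1] += (~is_C).sum()
            if is_C.any():
                occ_sum[k, 0] += rep_G[is_C].mean()
                occ_n[k, 0] += 1
            if (~is_C).any():
                occ_sum[k, 1] += rep_G[~is_C].mean()
                occ_n[k, 1] += 1
        # Re-scoring: image scorers record the seller's action, indifferent
        # scorers record G; either is flipped with probability mu.
        scored = buys
        intended_G = np.where(is_image[buyers], is_C, True)
        err = rng.random(n_sellers) < params.mu
        rep_G = np.where(scored, intended_G ^ err, rep_G)

    buyer_mean, buyer_se = _batch_se(pay_sum, pay_n)
    sell_mean, sell_se = _batch_se(sell_sum, sell_n)
    occ_mean, occ_se = _batch_se(occ_sum, occ_n)
    result = ABMResult(
        buyer_payoff=buyer_mean,
        buyer_payoff_se=buyer_se,
        buyer_games=pay_n.sum(axis=0),
        seller_C_payoff=float(sell_mean[0]),
        seller_C_payoff_se=float(sell_se[0]),
        seller_D_payoff=float(sell_mean[1]),
        seller_D_payoff_se=float(sell_se[1]),
        g_C=float(occ_mean[0]),
        g_C_se=float(occ_se[0]),
        g_D=float(occ_mean[1]),
        g_D_se=float(occ_se[1]),
        rounds_used=n_post,
        seed=config.seed,
    )
    return result, ts


def run_abm(config: ABMConfig) -> ABMResult:
    """Run the agent-based trust game and summarize payoffs and reputations."""
    result, _ = _simulate(config, record_timeseries=False)
    return result


def reputation_timeseries(config: ABMConfig):
    """Per-round fractions of good reputation among C and among D sellers."""
    import pandas as pd

    _, ts = _simulate(config, record_timeseries=True)
    return pd.DataFrame(
        {"round": np.arange(config.rounds), "g_C": ts[:, 0], "g_D": ts[:, 1]}
    )
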