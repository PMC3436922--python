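"""Core model: the trust game, seller reputation dynamics, and expected payoffs.

The game is an asymmetric social dilemma played between an infinite population
of buyers (investors) and sellers (trustees).  In a single encounter the buyer
first decides whether to buy.  No purchase leaves both players with 0.  If the
buyer buys, a cooperating (C) seller ships and both earn ``b`` (0 < b < 1); a
defecting (D) seller keeps the goods, earning the temptation payoff 1 while
the buyer is left with the negative ``exploited_payoff``.

Each seller carries a public binary reputation, good (G) or bad (B), updated
after every purchase by the buyer according to the buyer's scoring type:

* **image scorers** (fraction ``q``) assign G after shipping and B after
  exploitation;
* **indifferent scorers** (fraction ``1 - q``) always assign G.

Either way the assignment is flipped with probability ``mu`` (assignment
error), and a buyer's realized action deviates from the intended one with
probability ``eps`` (implementation error).  Reputations are untouched when no
purchase happens, so each seller's reputation follows a two-state Markov chain
whose transition rates depend on the composition of the buyer population.

This module provides the stationary reputation probabilities, the per-seller
reputation Markov chain and its eigendecomposition, and the closed-form
long-run expected payoffs of every buyer strategy and both seller strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STRATEGY_NAMES",
    "BUY",
    "DISC",
    "ANTIDISC",
    "NOBUY",
    "GameParams",
    "PopulationState",
    "BuyProbabilities",
    "ReputationEquilibrium",
    "PayoffProfile",
    "DegenerateChainError",
    "strategy_profile",
    "buy_probabilities",
    "reputation_fixed_point",
    "iterate_reputation",
    "transition_matrix",
    "markov_eigendecomposition",
    "expected_payoffs",
]

#: Buyer strategy order used throughout the package.
STRATEGY_NAMES = ("Buy", "Disc", "AntiDisc", "NoBuy")
BUY, DISC, ANTIDISC, NOBUY = range(4)

_SIMPLEX_TOL = 1e-9


class DegenerateChainError(ValueError):
    """Raised when a reputation chain has no unique stationary distribution."""


@dataclass(frozen=True)
class GameParams:
    """Scalar parameters of the trust game with a reputation mechanism.

    Parameters
    ----------
    b:
        Payoff to both players on a buy-and-ship transaction.  The social
        dilemma requires ``0 < b < 1``: the seller is tempted by the
        exploitation payoff 1 while mutual cooperation still beats no trade.
    exploited_payoff:
        Buyer's (negative) payoff when the seller defects after a purchase.
    mu:
        Assignment-error probability in [0, 1/2): the buyer records the
        reputation contrary to what the social norm prescribes.
    eps:
        Implementation-error probability in [0, 1/2): the buyer's realized
        buy/no-buy action deviates from the intended one.
    q:
        Fraction of image scorers among buyers, in [0, 1]; the remaining
        ``1 - q`` are indifferent scorers.
    """

    b: float = 0.5
    exploited_payoff: float = -1.0
    mu: float = 0.1
    eps: float = 0.1
    q: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.b < 1.0:
            raise ValueError(f"b must lie in (0, 1), got b={self.b}")
        if not self.exploited_payoff < 0.0:
            raise ValueError(
                "exploited_payoff must be negative (social-dilemma ordering "
                f"1 > b > 0 > exploited), got {self.exploited_payoff}"
            )
        if not 0.0 <= self.mu < 0.5:
            raise ValueError(f"mu must lie in [0, 1/2), got mu={self.mu}")
        if not 0.0 <= self.eps < 0.5:
            raise ValueError(f"eps must lie in [0, 1/2), got eps={self.eps}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got q={self.q}")

    @property
    def loss(self) -> float:
        """Magnitude of the exploited buyer's loss (``-exploited_payoff``)."""
        return -self.exploited_payoff

    @property
    def bad_prob_C(self) -> float:
        """Probability a C seller receives B after a purchase (both scorer types err alike)."""
        return self.mu

    @property
    def bad_prob_D(self) -> float:
        """Probability a D seller receives B after a purchase, averaged over scorer types.

        Image scorers assign B with probability ``1 - mu``, indifferent
        scorers with probability ``mu``; the scorer-type average is
        ``mu + q (1 - 2 mu)``, increasing in ``q``.
        """
        return self.mu + self.q * (1.0 - 2.0 * self.mu)


def strategy_profile(eps: float) -> np.ndarray:
    """Return the 4x2 array of (p_G, p_B) buy probabilities for the buyer strategies.

    Rows follow :data:`STRATEGY_NAMES`; columns are the probabilities of
    buying from a good- and a bad-reputation seller.  With implementation
    error ``eps`` the intended action is flipped with probability ``eps``:
    Buy = (1-eps, 1-eps), Disc = (1-eps, eps), AntiDisc = (eps, 1-eps),
    NoBuy = (eps, eps).
    """
    e = float(eps)
    return np.array(
        [[1 - e, 1 - e], [1 - e, e], [e, 1 - e], [e, e]]
    )


def _check_simplex(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (4,):
        raise ValueError(f"{name} must be a length-4 vector, got shape {v.shape}")
    for i, comp in enumerate(v):
        if comp < -_SIMPLEX_TOL:
            raise ValueError(
                f"{name}[{i}] = {comp} is negative (strategy {STRATEGY_NAMES[i]})"
            )
    if abs(v.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} must sum to 1, got sum {v.sum()!r}")
    return np.clip(v, 0.0, 1.0)


@dataclass(frozen=True)
class PopulationState:
    """Buyer strategy frequencies (per scorer type) and C-seller fraction.

    ``x`` holds the frequencies of (Buy, Disc, AntiDisc, NoBuy) among
    indifferent scorers, ``y`` among image scorers, and ``z`` is the fraction
    of C (shipping) sellers.  The analysis assumes scoring type and strategy
    are independent (``x == y``), a property preserved by the replicator flow
    because a buyer's payoff does not depend on its scorer type.  Pass
    ``allow_asymmetric=True`` to construct a state with ``x != y``.
    """

    x: np.ndarray
    z: float
    y: np.ndarray | None = None
    allow_asymmetric: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", _check_simplex(self.x, "x"))
        y = self.x if self.y is None else _check_simplex(self.y, "y")
        object.__setattr__(self, "y", y)
        if not self.allow_asymmetric and not np.allclose(self.x, self.y, atol=1e-8):
            raise ValueError(
                "scorer-type/strategy independence violated (x != y); "
                "pass allow_asymmetric=True to construct this state"
            )
        if not 0.0 <= self.z <= 1.0:
            raise ValueError(f"z must lie in [0, 1], got z={self.z}")


@dataclass(frozen=True)
class BuyProbabilities:
    """Buy probabilities toward G and B sellers, per scorer type and averaged."""

    pG_indifferent: float
    pB_indifferent: float
    pG_image: float
    pB_image: float
    pG: float  # q-weighted population average
    pB: float


def buy_probabilities(
    state: PopulationState, params: GameParams | None = None, eps: float | None = None
) -> BuyProbabilities:
    """Population buy probabilities toward G and B sellers.

    Each scorer type's probability is the mixture of the four strategies'
    (p_G, p_B) pairs weighted by that type's strategy frequencies; the
    population average weights the two types by ``1 - q`` and ``q``.
    """
    if params is not None:
        eps, q = params.eps, params.q
    elif eps is not None:
        q = 0.5  # only the per-type values are meaningful without params
    else:
        raise TypeError("either params or eps must be given")
    p = strategy_profile(eps)
    pG1, pB1 = float(state.x @ p[:, 0]), float(state.x @ p[:, 1])
    pG2, pB2 = float(state.y @ p[:, 0]), float(state.y @ p[:, 1])
    return BuyProbabilities(
        pG_indifferent=pG1,
        pB_indifferent=pB1,
        pG_image=pG2,
        pB_image=pB2,
        pG=(1 - q) * pG1 + q * pG2,
        pB=(1 - q) * pB1 + q * pB2,
    )


@dataclass(frozen=True)
class ReputationEquilibrium:
    """Stationary reputation probabilities and the buy probabilities behind them.

    ``g_C`` (``g_D``) is the stationary probability that a C (D) seller
    carries the good reputation; ``P_G`` and ``P_B`` are the population
    average probabilities that a random buyer buys from a G and a B seller.
    """

    g_C: float
    g_D: float
    P_G: float
    P_B: float


def _reputation_rates(
    params: GameParams, bp: BuyProbabilities
) -> tuple[float, float, float, float]:
    """Per-encounter up (B->G) and down (G->B) transition probabilities.

    Returns ``(up_C, down_C, up_D, down_D)``.  For a C seller both scorer
    types assign G with probability ``1 - mu`` after a purchase, so only the
    averaged buy probabilities enter.  For a D seller the assignment depends
    on the scorer type, so the scorer-specific buy probabilities are paired
    with the type-specific error rates.
    """
    mu, q = params.mu, params.q
    up_C = (1.0 - mu) * bp.pB
    down_C = mu * bp.pG
    # D seller: indifferent scorer assigns B w.p. mu, image scorer w.p. 1-mu.
    up_D = (1 - q) * bp.pB_indifferent * (1.0 - mu) + q * bp.pB_image * mu
    down_D = (1 - q) * bp.pG_indifferent * mu + q * bp.pG_image * (1.0 - mu)
    return up_C, down_C, up_D, down_D


def _stationary(up: float, down: float) -> float:
    total = up + down
    if total <= 0.0:
        # Reputations never move: frozen at the neutral initial average.
        return 0.5
    return up / total


def reputation_fixed_point(
    params: GameParams, state: PopulationState
) -> ReputationEquilibrium:
    """Closed-form stationary good-reputation probabilities for C and D sellers.

    The averaged reputation dynamics are linear birth-death flows
    ``g' = (1 - g) * up - g * down``; the fixed point is ``up / (up + down)``.
    ``g_C`` does not depend on ``q`` (both scorer types rate shipping sellers
    G with probability ``1 - mu``), whereas ``g_D`` decreases in ``q``.
    """
    bp = buy_probabilities(state, params)
    up_C, down_C, up_D, down_D = _reputation_rates(params, bp)
    return ReputationEquilibrium(
        g_C=_stationary(up_C, down_C),
        g_D=_stationary(up_D, down_D),
        P_G=bp.pG,
        P_B=bp.pB,
    )


def iterate_reputation(
    params: GameParams,
    state: PopulationState,
    g0: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> tuple[float, float]:
    """Fixed point of the averaged reputation dynamics by direct iteration.

    Iterates the one-step population-average update
    ``g <- g (1 - down) + (1 - g) up`` for C and D sellers from ``g0`` until
    the update falls below ``tol``.  This is the independent verification
    route for :func:`reputation_fixed_point`; the map is a contraction for
    every valid parameter set, so the cap only guards pathological inputs.
    """
    bp = buy_probabilities(state, params)
    up_C, down_C, up_D, down_D = _reputation_rates(params, bp)
    gs = []
    for up, down in ((up_C, down_C), (up_D, down_D)):
        g = g0
        for _ in range(max_iter):
            g_new = g * (1.0 - down) + (1.0 - g) * up
            if abs(g_new - g) < tol:
                g = g_new
                break
            g = g_new
        else:
            raise RuntimeError(
                f"reputation iteration did not converge within {max_iter} steps "
                f"(up={up}, down={down}, last g={g})"
            )
        gs.append(g)
    return gs[0], gs[1]


def transition_matrix(
    seller_strategy: str, params: GameParams, state: PopulationState
) -> np.ndarray:
    """Row-stochastic 2x2 reputation transition matrix for one seller type.

    States are ordered (G, B).  The reputation is unchanged when the matched
    buyer decides not to buy, so the off-diagonal entries are the
    per-encounter down (G->B) and up (B->G) probabilities.
    """
    if seller_strategy not in ("C", "D"):
        raise ValueError(f"seller_strategy must be 'C' or 'D', got {seller_strategy!r}")
    bp = buy_probabilities(state, params)
    up_C, down_C, up_D, down_D = _reputation_rates(params, bp)
    up, down = (up_C, down_C) if seller_strategy == "C" else (up_D, down_D)
    return np.array([[1.0 - down, down], [up, 1.0 - up]])


def markov_eigendecomposition(
    T: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Stationary vector, second eigenvalue, and its right eigenvector.

    For a nondegenerate 2x2 row-stochastic matrix ``T`` with off-diagonals
    ``a = T[0,1]`` and ``b = T[1,0]``, the decomposition
    ``T = 1 u + lam v w`` holds with stationary left vector
    ``u = (b, a)/(a+b)``, second eigenvalue ``lam = 1 - a - b``, right
    eigenvector ``v = (a, -b)/(a+b)`` and left eigenvector ``w = (1, -1)``,
    normalized so that ``u 1 = 1``, ``w v = 1``, ``u v = 0``, ``w 1 = 0``.
    """
    T = np.asarray(T, dtype=float)
    if T.shape != (2, 2):
        raise ValueError(f"T must be 2x2, got shape {T.shape}")
    if np.any(T < -1e-12) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("T must be row-stochastic")
    a, b = T[0, 1], T[1, 0]
    lam = 1.0 - a - b
    if a + b <= 1e-14:
        raise DegenerateChainError(
            "no unique stationary distribution: second eigenvalue equals 1 "
            "(reputation chain never moves)"
        )
    u = np.array([b, a]) / (a + b)
    v = np.array([a, -b]) / (a + b)
    return u, lam, v


@dataclass(frozen=True)
class PayoffProfile:
    """Long-run expected per-game payoffs at equilibrium reputations."""

    buyer: np.ndarray  # per strategy, order STRATEGY_NAMES
    seller_C: float
    seller_D: float
    reputation: ReputationEquilibrium


def expected_payoffs(params: GameParams, state: PopulationState) -> PayoffProfile:
    """Closed-form expected payoffs for the four buyer strategies and both sellers.

    In the long run each seller's reputation sits at its stationary
    distribution, so a buyer playing strategy ``i`` with buy probabilities
    ``(p_G, p_B)`` earns

    ``Pi_i = z b [g_C p_G + (1-g_C) p_B] + (1-z) exploited [g_D p_G + (1-g_D) p_B]``

    while sellers earn their transaction payoff times the stationary
    probability of being bought from:

    ``Pi_C = b [g_C P_G + (1-g_C) P_B]``,  ``Pi_D = g_D P_G + (1-g_D) P_B``.

    Every payoff is affine in ``z`` and in each buyer strategy frequency.
    """
    rep = reputation_fixed_point(params, state)
    p = strategy_profile(params.eps)
    buy_from_C = rep.g_C * p[:, 0] + (1.0 - rep.g_C) * p[:, 1]
    buy_from_D = rep.g_D * p[:, 0] + (1.0 - rep.g_D) * p[:, 1]
    buyer = (
        state.z * params.b * buy_from_C
        + (1.0 - state.z) * params.exploited_payoff * buy_from_D
    )
    seller_C = params.b * (rep.g_C * rep.P_G + (1.0 - rep.g_C) * rep.P_B)
    seller_D = rep.g_D * rep.P_G + (1.0 - rep.g_D) * rep.P_B
    return PayoffProfile(
        buyer=buyer, seller_C=float(seller_C), seller_D=float(seller_D), reputation=rep
    )
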