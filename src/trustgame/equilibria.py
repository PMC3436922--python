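"""Nash equilibria of the reputation-mediated trust game and their stability.

The game has exactly three types of Nash equilibria:

* the **uncooperative equilibrium** — all buyers play NoBuy and all sellers
  defect; it always exists and is strict;
* the **cooperative equilibrium** — buyers mix Buy and Disc, sellers mix C
  and D with a high C fraction; it exists iff the image-scorer fraction and
  payoffs satisfy the existence condition below, and is then asymptotically
  stable under the replicator dynamics;
* a **singular equilibrium** — pure Disc against a line segment of seller
  mixtures, present only on the knife-edge where the existence condition
  holds with equality.

Writing ``m = mu`` for the probability that a shipping seller is scored B and
``M = mu + q (1 - 2 mu)`` for the same probability for a defecting seller,
the seller-indifference ratio at the cooperative point is

    P_B / P_G = (b M - m) / ((1 - m) - b (1 - M)),

and the cooperative equilibrium exists iff

    b (eps + M (1 - 2 eps))  >  eps + m (1 - 2 eps),

i.e. iff the bad reputation earned from image scorers outweighs the seller's
temptation.  Solving the equality for ``q`` gives the minimal image-scorer
fraction that sustains cooperation.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .core import (
    ANTIDISC,
    BUY,
    DISC,
    NOBUY,
    GameParams,
    PopulationState,
    expected_payoffs,
    reputation_fixed_point,
)

__all__ = [
    "EquilibriumReport",
    "StabilityReport",
    "existence_margin",
    "cooperative_exists",
    "uncooperative_equilibrium",
    "cooperative_equilibrium",
    "singular_equilibrium",
    "cooperative_stability",
    "reduced_rhs",
    "image_scorer_threshold",
    "scan_equilibrium_surface",
    "approximate_nash_points",
    "deviation_gains",
]


@dataclass(frozen=True)
class EquilibriumReport:
    """A located equilibrium: type, coordinates, existence and stability."""

    kind: str  # "uncooperative" | "cooperative" | "singular"
    exists: bool
    buyer_mix: np.ndarray | None = None
    z: float | None = None
    stability: str | None = None  # "strict_nash" | "asymptotically_stable" | "neutral"
    eigenvalues: tuple[complex, complex] | None = None
    z_interval: tuple[float, float] | None = None  # singular line only

    def state(self) -> PopulationState:
        if not self.exists or self.buyer_mix is None:
            raise ValueError(f"the {self.kind} equilibrium has no point coordinates")
        return PopulationState(x=self.buyer_mix, z=self.z)


def existence_margin(params: GameParams, q: float | None = None) -> float:
    """Signed margin of the cooperative-equilibrium existence condition.

    Positive iff ``b (eps + M (1-2 eps)) > eps + mu (1-2 eps)`` where
    ``M = mu + q (1 - 2 mu)``.  ``q`` overrides ``params.q`` when given.
    """
    mu, eps, b = params.mu, params.eps, params.b
    if q is None:
        q = params.q
    M = mu + q * (1.0 - 2.0 * mu)
    return b * (eps + M * (1.0 - 2.0 * eps)) - (eps + mu * (1.0 - 2.0 * eps))


def cooperative_exists(params: GameParams) -> bool:
    return existence_margin(params) > 0.0


def deviation_gains(params: GameParams, state: PopulationState) -> tuple[float, float]:
    """Best unilateral deviation gains (buyer, seller) at a population state.

    Payoffs are linear in the deviator's own mixture, so the best deviation
    is a pure strategy; a state is (approximately) Nash when both gains are
    (approximately) non-positive.
    """
    prof = expected_payoffs(params, state)
    buyer_mean = float(state.x @ prof.buyer)
    buyer_gain = float(prof.buyer.max()) - buyer_mean
    seller_mean = state.z * prof.seller_C + (1.0 - state.z) * prof.seller_D
    seller_gain = max(prof.seller_C, prof.seller_D) - seller_mean
    return buyer_gain, seller_gain


def uncooperative_equilibrium(params: GameParams) -> EquilibriumReport:
    """The always-present strict equilibrium: NoBuy buyers, all-D sellers.

    Strictness is verified directly: every unilateral pure deviation loses.
    With ``eps = 0`` nobody transacts and the seller side of the comparison
    degenerates to a tie, so the numeric verification is meaningful for
    ``eps > 0``; the equilibrium is labelled strict either way.
    """
    mix = np.array([0.0, 0.0, 0.0, 1.0])
    return EquilibriumReport(
        kind="uncooperative", exists=True, buyer_mix=mix, z=0.0, stability="strict_nash"
    )


def _cooperative_point(params: GameParams) -> tuple[float, float] | None:
    """(x_Buy*, z*) of the cooperative equilibrium, or None if absent."""
    if existence_margin(params) <= 0.0:
        return None
    mu, eps, b, c = params.mu, params.eps, params.b, params.loss
    M = params.bad_prob_D
    # Seller indifference b Pi_D-chain == Pi_C-chain fixes P_B / P_G.
    ratio = (b * M - mu) / ((1.0 - mu) - b * (1.0 - M))
    pG = 1.0 - eps
    pB = ratio * pG
    x_buy = (pB - eps) / (1.0 - 2.0 * eps)
    # Buyer indifference between Buy and Disc fixes z.
    g_C = (1.0 - mu) * pB / ((1.0 - mu) * pB + mu * pG)
    g_D = (1.0 - M) * pB / ((1.0 - M) * pB + M * pG)
    z = c * (1.0 - g_D) / (c * (1.0 - g_D) + b * (1.0 - g_C))
    return x_buy, z


def cooperative_equilibrium(params: GameParams) -> EquilibriumReport:
    """Closed-form Buy/Disc mixture with an interior C-seller fraction.

    At the returned point the Buy and Disc payoffs coincide, the C and D
    seller payoffs coincide, and both AntiDisc and NoBuy earn strictly less
    (because ``g_C > g_D`` whenever ``q > 0``).
    """
    pt = _cooperative_point(params)
    if pt is None:
        return EquilibriumReport(kind="cooperative", exists=False)
    x_buy, z = pt
    mix = np.array([x_buy, 1.0 - x_buy, 0.0, 0.0])
    stab = cooperative_stability(params)
    return EquilibriumReport(
        kind="cooperative",
        exists=True,
        buyer_mix=mix,
        z=z,
        stability="asymptotically_stable" if stab.stable else "unstable",
        eigenvalues=stab.eigenvalues,
    )


def singular_equilibrium(
    params: GameParams, tol: float = 1e-12
) -> EquilibriumReport | None:
    """Knife-edge equilibrium: pure Disc with a line of seller mixtures.

    Exists only when the existence condition holds with equality (within
    ``tol``), which makes the two seller strategies payoff-equivalent against
    pure Disc for *every* seller mixture; ``z`` may then take any value for
    which Disc best-responds.  Generic parameters return ``None``.
    """
    if abs(existence_margin(params)) > tol:
        return None
    mu, eps, b, c = params.mu, params.eps, params.b, params.loss
    M = params.bad_prob_D
    pG, pB = 1.0 - eps, eps
    g_C = (1.0 - mu) * pB / ((1.0 - mu) * pB + mu * pG) if pB + pG > 0 else 0.5
    g_D = (1.0 - M) * pB / ((1.0 - M) * pB + M * pG) if pB + pG > 0 else 0.5
    # Disc best-responds iff the payoff coefficient of p_G is >= 0 and that of
    # p_B is <= 0, which brackets z between the two indifference values.
    z_lo = c * g_D / (c * g_D + b * g_C) if (c * g_D + b * g_C) > 0 else 0.0
    z_hi = c * (1.0 - g_D) / (c * (1.0 - g_D) + b * (1.0 - g_C))
    mix = np.array([0.0, 1.0, 0.0, 0.0])
    return EquilibriumReport(
        kind="singular",
        exists=True,
        buyer_mix=mix,
        z=0.5 * (z_lo + z_hi),
        stability="neutral",
        z_interval=(z_lo, z_hi),
    )


# ---------------------------------------------------------------------------
# Stability of the cooperative equilibrium
# ---------------------------------------------------------------------------

def reduced_rhs(x1: float, z: float, params: GameParams) -> tuple[float, float]:
    """Replicator vector field restricted to the Buy/Disc face.

    State is (fraction of Buy among buyers, fraction of C sellers); AntiDisc
    and NoBuy are absent.  This face is invariant under the full dynamics.
    """
    mu, eps, b, c = params.mu, params.eps, params.b, params.loss
    M = params.bad_prob_D
    pG = 1.0 - eps
    pB = eps + x1 * (1.0 - 2.0 * eps)
    D_C = (1.0 - mu) * pB + mu * pG
    D_D = (1.0 - M) * pB + M * pG
    g_C = (1.0 - mu) * pB / D_C
    g_D = (1.0 - M) * pB / D_D
    coef_B = z * b * (1.0 - g_C) - (1.0 - z) * c * (1.0 - g_D)
    f1 = x1 * (1.0 - x1) * (1.0 - 2.0 * eps) * coef_B
    f2 = z * (1.0 - z) * (b * pG * pB / D_C - pG * pB / D_D)
    return f1, f2


@lru_cache(maxsize=1)
def _symbolic_jacobian():
    """Lambdified analytic Jacobian of the reduced system (sympy, cached)."""
    import sympy as sp

    x1, z, b, c, mu, eps, M = sp.symbols("x1 z b c mu eps M", positive=True)
    pG = 1 - eps
    pB = eps + x1 * (1 - 2 * eps)
    D_C = (1 - mu) * pB + mu * pG
    D_D = (1 - M) * pB + M * pG
    g_C = (1 - mu) * pB / D_C
    g_D = (1 - M) * pB / D_D
    coef_B = z * b * (1 - g_C) - (1 - z) * c * (1 - g_D)
    f1 = x1 * (1 - x1) * (1 - 2 * eps) * coef_B
    f2 = z * (1 - z) * (b * pG * pB / D_C - pG * pB / D_D)
    J = sp.Matrix([f1, f2]).jacobian([x1, z])
    return sp.lambdify((x1, z, b, c, mu, eps, M), J, modules="numpy")


@dataclass(frozen=True)
class StabilityReport:
    """Jacobian diagnostics of the cooperative equilibrium."""

    jacobian: np.ndarray  # analytic (symbolically differentiated)
    jacobian_fd: np.ndarray  # central finite differences of the numeric RHS
    trace: float
    determinant: float
    eigenvalues: tuple[complex, complex]
    stable: bool


def cooperative_stability(params: GameParams, fd_step: float = 1e-6) -> StabilityReport:
    """Linear stability of the cooperative equilibrium in the reduced system.

    The Jacobian is computed twice — symbolically and by central differences
    of :func:`reduced_rhs` — and both are reported.  The equilibrium is
    asymptotically stable iff ``trace < 0`` and ``det > 0``.  Note that the
    seller payoff difference does not depend on ``z``, so the (z, z) entry is
    exactly zero and the determinant reduces to ``-J12 * J21``.
    """
    pt = _cooperative_point(params)
    if pt is None:
        raise ValueError(
            "cooperative equilibrium does not exist for these parameters "
            f"(existence margin {existence_margin(params):.3g} <= 0)"
        )
    x1, z = pt
    J = np.asarray(
        _symbolic_jacobian()(
            x1, z, params.b, params.loss, params.mu, params.eps, params.bad_prob_D
        ),
        dtype=float,
    )
    h = fd_step
    J_fd = np.empty((2, 2))
    for j, (dx, dz) in enumerate(((h, 0.0), (0.0, h))):
        fp = reduced_rhs(x1 + dx, z + dz, params)
        fm = reduced_rhs(x1 - dx, z - dz, params)
        J_fd[0, j] = (fp[0] - fm[0]) / (2 * h)
        J_fd[1, j] = (fp[1] - fm[1]) / (2 * h)
    tr, det = float(np.trace(J)), float(np.linalg.det(J))
    eig = np.linalg.eigvals(J)
    return StabilityReport(
        jacobian=J,
        jacobian_fd=J_fd,
        trace=tr,
        determinant=det,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stable=tr < 0.0 and det > 0.0,
    )


# ---------------------------------------------------------------------------
# Threshold and parameter scans
# ---------------------------------------------------------------------------

def image_scorer_threshold(
    params: GameParams, tol: float = 1e-10, prescan: int = 21
) -> float | None:
    """Minimal image-scorer fraction ``q*`` sustaining the cooperative equilibrium.

    Solves the existence condition's equality for ``q`` by bisection on
    [0, 1].  The margin is monotone increasing in ``q`` (the defector's bad
    reputation probability ``M`` grows with ``q``); a coarse pre-scan asserts
    this before bisecting.  Returns ``None`` when even ``q = 1`` fails, and
    ``0.0`` when the condition already holds without image scorers.
    """
    margins = [existence_margin(params, q=qi) for qi in np.linspace(0.0, 1.0, prescan)]
    if any(b < a - 1e-15 for a, b in itertools.pairwise(margins)):
        raise RuntimeError("existence margin is not monotone in q")
    if margins[-1] <= 0.0:
        return None
    if margins[0] > 0.0:
        return 0.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if existence_margin(params, q=mid) > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def scan_equilibrium_surface(
    params: GameParams,
    x_param: str,
    x_values: np.ndarray,
    y_param: str,
    y_values: np.ndarray,
):
    """Tidy table of cooperative-equilibrium existence and coordinates on a grid.

    Varies two ``GameParams`` fields over the given values; each row reports
    whether the cooperative equilibrium exists there and, if so, its Buy
    probability, C-seller fraction, and stability verdict.
    """
    import pandas as pd

    rows = []
    for xv in np.asarray(x_values, dtype=float):
        for yv in np.asarray(y_values, dtype=float):
            p = dataclasses.replace(params, **{x_param: float(xv), y_param: float(yv)})
            rec = {x_param: float(xv), y_param: float(yv)}
            if cooperative_exists(p):
                x1, z = _cooperative_point(p)
                stab = cooperative_stability(p)
                rec.update(exists=True, x_buy=x1, z=z, stable=stab.stable)
            else:
                rec.update(exists=False, x_buy=np.nan, z=np.nan, stable=False)
            rows.append(rec)
    return pd.DataFrame(rows, columns=[x_param, y_param, "exists", "x_buy", "z", "stable"])


# ---------------------------------------------------------------------------
# Brute-force verifier
# ---------------------------------------------------------------------------

def _simplex_grid(step: float) -> np.ndarray:
    """All points of the 4-simplex with coordinates that are multiples of step."""
    n = round(1.0 / step)
    pts = [
        (i / n, j / n, k / n, (n - i - j - k) / n)
        for i in range(n + 1)
        for j in range(n + 1 - i)
        for k in range(n + 1 - i - j)
    ]
    return np.array(pts)


def approximate_nash_points(
    params: GameParams, mix_step: float = 0.1, z_step: float = 0.05, tol: float = 1e-6
) -> np.ndarray:
    """Exhaustive approximate-Nash search over a discretized state space.

    Evaluates every grid point of (buyer 4-simplex) x [0, 1] and returns the
    states (rows ``[x1, x2, x3, x4, z]``) at which no unilateral deviation
    gains more than ``tol``.  This is the independent verification route for
    the equilibrium catalogue; it relies on nothing but the payoff formulas
    and linearity of payoffs in the deviator's own mixture.
    """
    from .core import strategy_profile

    mu, eps, b, c, q = params.mu, params.eps, params.b, params.loss, params.q
    M = params.bad_prob_D
    X = _simplex_grid(mix_step)  # (N, 4)
    p = strategy_profile(eps)
    pG = X @ p[:, 0]
    pB = X @ p[:, 1]
    D_C = (1.0 - mu) * pB + mu * pG
    D_D = (1.0 - M) * pB + M * pG
    with np.errstate(invalid="ignore", divide="ignore"):
        g_C = np.where(D_C > 0, (1.0 - mu) * pB / np.where(D_C > 0, D_C, 1.0), 0.5)
        g_D = np.where(D_D > 0, (1.0 - M) * pB / np.where(D_D > 0, D_D, 1.0), 0.5)
    buy_from_C = np.outer(g_C, p[:, 0]) + np.outer(1.0 - g_C, p[:, 1])  # (N, 4)
    buy_from_D = np.outer(g_D, p[:, 0]) + np.outer(1.0 - g_D, p[:, 1])
    seller_C = b * (g_C * pG + (1.0 - g_C) * pB)  # (N,)
    seller_D = g_D * pG + (1.0 - g_D) * pB
    zs = np.arange(0.0, 1.0 + 0.5 * z_step, z_step)  # (Nz,)
    hits = []
    for z in zs:
        buyer = z * b * buy_from_C + (1.0 - z) * (-c) * buy_from_D  # (N, 4)
        mean = np.einsum("ij,ij->i", X, buyer)
        buyer_gain = buyer.max(axis=1) - mean
        seller_mean = z * seller_C + (1.0 - z) * seller_D
        seller_gain = np.maximum(seller_C, seller_D) - seller_mean
        ok = (buyer_gain <= tol) & (seller_gain <= tol)
        for i in np.nonzero(ok)[0]:
            hits.append([*X[i], z])
    return np.array(hits).reshape(-1, 5)
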