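"""Two-population replicator dynamics, attractor classification, basin volumes.

Buyers and sellers evolve separately: a buyer strategy grows when its
expected payoff exceeds the buyer population mean, and the C-seller fraction
grows when shipping outperforms defecting,

    dx_i/dt = x_i (Pi_i - sum_j x_j Pi_j),      i in {Buy, Disc, AntiDisc, NoBuy},
    dz/dt   = z (1 - z) (Pi_C - Pi_D),

with all payoffs evaluated at the quasi-stationary reputation distribution
for the current population state (reputations equilibrate much faster than
strategies).  The flow preserves the buyer simplex, keeps every boundary
face invariant, and preserves the independence of scoring type and strategy:
a buyer's payoff does not depend on whether it is an image or indifferent
scorer, so equal strategy frequencies in the two scorer classes stay equal.

The long-run behaviour is bistable: trajectories converge either to the
uncooperative corner (NoBuy / all-D) or, when it exists, to the cooperative
Buy-Disc mixture.  :func:`basin_volume` measures the relative size of the
cooperative basin under uniform initial conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import RK45, solve_ivp

from .core import GameParams, PopulationState, strategy_profile
from .equilibria import _cooperative_point, cooperative_exists

__all__ = [
    "Trajectory",
    "BasinEstimate",
    "replicator_rhs",
    "replicator_rhs_split",
    "attractor_points",
    "integrate",
    "basin_volume",
]

logger = logging.getLogger(__name__)

#: Classification distance to an attractor (Euclidean, full (x, z) state).
DEFAULT_DELTA = 1e-3
#: First classification horizon; doubled until DEFAULT_MAX_HORIZON on failure.
DEFAULT_HORIZON = 1e4
DEFAULT_MAX_HORIZON = 1e6


def _payoff_pieces(u: np.ndarray, params: GameParams):
    """Buyer payoff vector and seller payoffs for symmetric states.

    ``u`` has rows ``[x1, x2, x3, x4, z]``; works on a single state (shape
    ``(5,)``) or a batch (shape ``(n, 5)``).
    """
    single = u.ndim == 1
    U = u[None, :] if single else u
    x, z = U[:, :4], U[:, 4]
    mu, eps, b, c = params.mu, params.eps, params.b, params.loss
    M = params.bad_prob_D
    p = strategy_profile(eps)
    pG = x @ p[:, 0]
    pB = x @ p[:, 1]
    D_C = (1.0 - mu) * pB + mu * pG
    D_D = (1.0 - M) * pB + M * pG
    g_C = np.where(D_C > 0.0, (1.0 - mu) * pB / np.where(D_C > 0.0, D_C, 1.0), 0.5)
    g_D = np.where(D_D > 0.0, (1.0 - M) * pB / np.where(D_D > 0.0, D_D, 1.0), 0.5)
    buy_from_C = np.outer(g_C, p[:, 0]) + np.outer(1.0 - g_C, p[:, 1])
    buy_from_D = np.outer(g_D, p[:, 0]) + np.outer(1.0 - g_D, p[:, 1])
    buyer = z[:, None] * b * buy_from_C - (1.0 - z)[:, None] * c * buy_from_D
    seller_C = b * (g_C * pG + (1.0 - g_C) * pB)
    seller_D = g_D * pG + (1.0 - g_D) * pB
    if single:
        return buyer[0], seller_C[0], seller_D[0]
    return buyer, seller_C, seller_D


def replicator_rhs(
    u: np.ndarray,
    params: GameParams,
    rate_buyer: float = 1.0,
    rate_seller: float = 1.0,
) -> np.ndarray:
    """Time derivative of ``[x1..x4, z]`` (symmetric scorer classes, x == y).

    ``rate_buyer`` and ``rate_seller`` rescale the adaptation speed of the
    two populations; rescaling changes the time parametrization of orbits
    but not their terminal classification.
    """
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    U = u[None, :] if single else u
    buyer, seller_C, seller_D = _payoff_pieces(U, params)
    x, z = U[:, :4], U[:, 4]
    mean = np.einsum("ij,ij->i", x, buyer)
    dx = rate_buyer * x * (buyer - mean[:, None])
    dz = rate_seller * z * (1.0 - z) * (seller_C - seller_D)
    out = np.concatenate([dx, dz[:, None]], axis=1)
    return out[0] if single else out


def replicator_rhs_split(u: np.ndarray, params: GameParams) -> np.ndarray:
    """Time derivative of ``[x1..x4, y1..y4, z]`` with separate scorer classes.

    ``x`` are strategy frequencies among indifferent scorers, ``y`` among
    image scorers.  The two classes experience identical strategy payoffs
    (payoffs depend on population-level reputations only), so the subspace
    ``x == y`` is invariant — the property the symmetric reduction relies on.
    """
    u = np.asarray(u, dtype=float)
    x, y, z = u[:4], u[4:8], u[8]
    mu, eps, b, c, q = params.mu, params.eps, params.b, params.loss, params.q
    p = strategy_profile(eps)
    pG1, pB1 = x @ p[:, 0], x @ p[:, 1]
    pG2, pB2 = y @ p[:, 0], y @ p[:, 1]
    pG = (1 - q) * pG1 + q * pG2
    pB = (1 - q) * pB1 + q * pB2
    up_C, down_C = (1 - mu) * pB, mu * pG
    up_D = (1 - q) * pB1 * (1 - mu) + q * pB2 * mu
    down_D = (1 - q) * pG1 * mu + q * pG2 * (1 - mu)
    g_C = up_C / (up_C + down_C) if up_C + down_C > 0 else 0.5
    g_D = up_D / (up_D + down_D) if up_D + down_D > 0 else 0.5
    buyer = z * b * (g_C * p[:, 0] + (1 - g_C) * p[:, 1]) - (1 - z) * c * (
        g_D * p[:, 0] + (1 - g_D) * p[:, 1]
    )
    dx = x * (buyer - x @ buyer)
    dy = y * (buyer - y @ buyer)
    seller_C = b * (g_C * pG + (1 - g_C) * pB)
    seller_D = g_D * pG + (1 - g_D) * pB
    dz = z * (1 - z) * (seller_C - seller_D)
    return np.concatenate([dx, dy, [dz]])


def attractor_points(params: GameParams) -> dict[str, np.ndarray]:
    """The point attractors of the flow: uncooperative corner and, when it
    exists, the cooperative Buy/Disc equilibrium."""
    pts = {"uncooperative": np.array([0.0, 0.0, 0.0, 1.0, 0.0])}
    if cooperative_exists(params):
        x1, z = _cooperative_point(params)
        pts["cooperative"] = np.array([x1, 1.0 - x1, 0.0, 0.0, z])
    return pts


def _classify(u: np.ndarray, attractors: dict[str, np.ndarray], delta: float) -> str:
    for name, pt in attractors.items():
        if np.linalg.norm(u - pt) < delta:
            return name
    return "undecided"


def _project(u: np.ndarray) -> np.ndarray:
    """Re-project a (batch of) state(s) onto the simplex x [0, 1] after drift."""
    U = np.atleast_2d(u)
    tiny = (U[:, :4] < 0.0) & (U[:, :4] > -1e-15)
    if np.any(U[:, :4] < -1e-15):
        worst = U[:, :4].min()
        logger.debug("clipping replicator state below -1e-15 (min %.3e)", worst)
    U[:, :4] = np.clip(U[:, :4], 0.0, None)
    del tiny
    s = U[:, :4].sum(axis=1)
    bad = np.abs(s - 1.0) > 1e-12
    if np.any(bad):
        U[bad, :4] /= s[bad, None]
    U[:, 4] = np.clip(U[:, 4], 0.0, 1.0)
    return U[0] if u.ndim == 1 else U


@dataclass(frozen=True)
class Trajectory:
    """An integrated orbit with its terminal classification."""

    t: np.ndarray
    x: np.ndarray  # (n_times, 4)
    z: np.ndarray  # (n_times,)
    classification: str  # "cooperative" | "uncooperative" | "undecided"

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(x=_project(np.append(self.x[-1], self.z[-1]))[:4],
                               z=float(np.clip(self.z[-1], 0.0, 1.0)))


def integrate(
    state0: PopulationState,
    params: GameParams,
    horizon: float = DEFAULT_HORIZON,
    max_horizon: float = DEFAULT_MAX_HORIZON,
    delta: float = DEFAULT_DELTA,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    rate_buyer: float = 1.0,
    rate_seller: float = 1.0,
) -> Trajectory:
    """Adaptive integration of one orbit with attractor classification.

    Integrates until the state comes within ``delta`` of an attractor
    (terminal event) or the horizon is reached; an unclassified orbit has
    its horizon doubled up to ``max_horizon`` before being marked
    ``undecided``.  The state is re-projected onto the simplex whenever
    solver drift exceeds 1e-12.
    """
    attractors = attractor_points(params)
    u0 = np.append(state0.x, state0.z).astype(float)

    def rhs(t, u):
        if not np.all(np.isfinite(u)):
            raise FloatingPointError(f"non-finite replicator state at t={t}: {u}")
        return replicator_rhs(_project(u.copy()), params, rate_buyer, rate_seller)

    events = []
    for pt in attractors.values():
        def ev(t, u, pt=pt):
            return float(np.linalg.norm(u - pt) - delta)
        ev.terminal = True
        events.append(ev)

    ts, us = [np.array([0.0])], [u0[None, :]]
    t0, T = 0.0, horizon
    names = list(attractors)
    label = _classify(u0, attractors, delta)
    while label == "undecided":
        sol = solve_ivp(
            rhs, (t0, T), u0, method="RK45", rtol=rtol, atol=atol, events=events,
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"replicator integration failed: {sol.message}")
        ts.append(sol.t[1:])
        us.append(_project(sol.y.T[1:].copy()))
        u0 = _project(sol.y[:, -1].copy())
        t0 = sol.t[-1]
        if sol.status == 1:  # a terminal proximity event fired
            label = next(
                names[i] for i, te in enumerate(sol.t_events) if te.size > 0
            )
            break
        label = _classify(u0, attractors, delta)
        if label == "undecided":
            if T >= max_horizon:
                break
            T = min(2 * T, max_horizon)
    t = np.concatenate(ts)
    U = np.vstack(us)
    return Trajectory(t=t, x=U[:, :4], z=U[:, 4], classification=label)


# ---------------------------------------------------------------------------
# Monte-Carlo basin measurement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasinEstimate:
    """Relative volume of the cooperative basin under uniform initial states."""

    volume: float
    n_samples: int
    ci_low: float
    ci_high: float
    n_cooperative: int
    n_uncooperative: int
    n_undecided: int
    seed: int

    @property
    def uncooperative_volume(self) -> float:
        return self.n_uncooperative / self.n_samples

    @property
    def undecided_fraction(self) -> float:
        return self.n_undecided / self.n_samples


def _integrate_batch(
    U0: np.ndarray,
    params: GameParams,
    attractors: dict[str, np.ndarray],
    delta: float,
    max_horizon: float,
    rtol: float,
    atol: float,
    rate_buyer: float = 1.0,
    rate_seller: float = 1.0,
) -> np.ndarray:
    """Classify a batch of initial states; returns an integer label array.

    All orbits are advanced together by one adaptive RK45 solver acting on
    the stacked system; at periodic checkpoints converged orbits are retired
    and the solver is rebuilt on the survivors.  Labels: 0 uncooperative,
    1 cooperative, -1 undecided.
    """
    n = U0.shape[0]
    labels = np.full(n, -1, dtype=int)
    active = np.arange(n)
    U = U0.copy()
    names = list(attractors)
    pts = np.array([attractors[k] for k in names])
    codes = np.array([0 if k == "uncooperative" else 1 for k in names])

    t, chunk = 0.0, 25.0
    while active.size and t < max_horizon:
        m = active.size

        def flat_rhs(_t, v):
            W = _project(v.reshape(m, 5).copy())
            return replicator_rhs(W, params, rate_buyer, rate_seller).ravel()

        solver = RK45(
            flat_rhs, t, U[active].ravel(), t_bound=min(t + chunk, max_horizon),
            rtol=rtol, atol=atol,
        )
        while solver.status == "running":
            solver.step()
        if solver.status == "failed":
            raise RuntimeError("batch replicator integration failed")
        t = solver.t
        U[active] = _project(solver.y.reshape(m, 5).copy())
        d = np.linalg.norm(U[active][:, None, :] - pts[None, :, :], axis=2)  # (m, k)
        hit = d.min(axis=1) < delta
        if np.any(hit):
            which = d.argmin(axis=1)
            labels[active[hit]] = codes[which[hit]]
            active = active[~hit]
        chunk *= 2.0
    return labels


def basin_volume(
    params: GameParams,
    n_samples: int,
    seed: int,
    restrict: int = 3,
    delta: float = DEFAULT_DELTA,
    max_horizon: float = DEFAULT_MAX_HORIZON,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> BasinEstimate:
    """Monte-Carlo volume of the cooperative basin of attraction.

    Initial buyer mixtures are uniform on the 3-simplex over (Buy, Disc,
    NoBuy) when ``restrict=3`` (the AntiDisc-free prism) or on the full
    4-simplex when ``restrict=4``; the C-seller fraction is uniform on
    (0, 1).  Uniform simplex sampling uses the symmetric Dirichlet(1,...,1)
    construction.  The 95% interval is the Wilson score interval for the
    binomial cooperative count.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if restrict not in (3, 4):
        raise ValueError(f"restrict must be 3 or 4, got {restrict}")
    rng = np.random.default_rng(seed)
    if restrict == 3:
        w = rng.dirichlet(np.ones(3), size=n_samples)
        x = np.zeros((n_samples, 4))
        x[:, [0, 1, 3]] = w  # Buy, Disc, NoBuy; AntiDisc absent
    else:
        x = rng.dirichlet(np.ones(4), size=n_samples)
    z = rng.uniform(0.0, 1.0, size=n_samples)
    U0 = np.concatenate([x, z[:, None]], axis=1)
    attractors = attractor_points(params)
    labels = _integrate_batch(U0, params, attractors, delta, max_horizon, rtol, atol)
    n_coop = int(np.sum(labels == 1))
    n_unco = int(np.sum(labels == 0))
    n_und = int(np.sum(labels == -1))
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(n_coop, n_samples, alpha=0.05, method="wilson")
    return BasinEstimate(
        volume=n_coop / n_samples,
        n_samples=n_samples,
        ci_low=float(lo),
        ci_high=float(hi),
        n_cooperative=n_coop,
        n_uncooperative=n_unco,
        n_undecided=n_und,
        seed=seed,
    )
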