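import numpy as np
import pytest

from trustgame import GameParams, PopulationState


def random_params(rng, eps_min=0.0, mu_min=0.0, q_min=0.0, q_max=1.0) -> GameParams:
    """A generic parameter draw covering the valid region."""
    return GameParams(
        b=float(rng.uniform(0.05, 0.95)),
        exploited_payoff=float(-rng.uniform(0.2, 2.0)),
        mu=float(rng.uniform(mu_min, 0.45)),
        eps=float(rng.uniform(eps_min, 0.45)),
        q=float(rng.uniform(q_min, q_max)),
    )


def random_state(rng, interior=False) -> PopulationState:
    """Uniform state; ``interior=True`` keeps all strategies clearly present."""
    alpha = 3.0 if interior else 1.0
    x = rng.dirichlet(np.full(4, alpha))
    z = float(rng.uniform(0.2, 0.8) if interior else rng.uniform(0.0, 1.0))
    return PopulationState(x=x, z=z)


def cooperative_params(rng, max_tries=1000) -> GameParams:
    """Rejection-sample parameters admitting the cooperative equilibrium."""
    from trustgame import cooperative_exists

    for _ in range(max_tries):
        p = random_params(rng, eps_min=0.01, q_min=0.05)
        if cooperative_exists(p):
            return p
    raise RuntimeError("could not sample parameters with a cooperative equilibrium")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
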