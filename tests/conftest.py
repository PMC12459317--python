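import numpy as np
import pytest

from glycpath import CtmcStructure, IntervalCounts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_structure():
    """Single irreversible transition 1 -> 2 with unit intensity."""
    return CtmcStructure(states=("A", "B"), absorbing=frozenset({"B"}),
                         allowed=((0, 1),))


@pytest.fixture
def q_two_state():
    return np.array([[-1.0, 1.0], [0.0, 0.0]])


@pytest.fixture
def bi_structure():
    """Three-state pathway structure: N <-> P -> D, D absorbing."""
    return CtmcStructure(states=("N", "P", "D"), absorbing=frozenset({"D"}),
                         allowed=((0, 1), (0, 2), (1, 0), (1, 2)))


def random_generator(rng, n=3, absorbing=(2,), scale=0.5):
    """A random valid generator with the given absorbing rows."""
    q = rng.uniform(0.05, scale, size=(n, n))
    np.fill_diagonal(q, 0.0)
    for i in absorbing:
        q[i] = 0.0
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


@pytest.fixture
def random_q(rng):
    return random_generator(rng)


def simulate_panel_counts(q, structure, n_subjects, horizon, interval, rng,
                          initial_probs=None):
    """Direct latent-state panel observation, aggregated to IntervalCounts."""
    from glycpath import sample_trajectory

    k = len(structure.states)
    transient = structure.transient_indices
    if initial_probs is None:
        initial_probs = np.zeros(k)
        initial_probs[transient[0]] = 1.0
    schedule = np.arange(0, horizon + 1e-9, interval)
    counts = IntervalCounts()
    for _ in range(n_subjects):
        s0 = rng.choice(k, p=initial_probs)
        traj = sample_trajectory(q, s0, horizon, rng)
        obs = [traj.state_at(t) for t in schedule]
        for a, b in zip(obs[:-1], obs[1:]):
            if structure.states[a] in structure.absorbing:
                break
            counts.add(structure.states[a], structure.states[b], interval)
    return counts
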