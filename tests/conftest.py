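"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
import scipy.stats

import betapairhmm as bp


def random_sample_model(rng: np.random.Generator, sample_id: str = "rand") -> bp.SampleModel:
    """A random, structurally valid full model (for oracle-equivalence tests)."""
    emissions = {}
    for a in bp.LOCATION_CLASSES:
        params = {}
        for k in bp.allowed_states(a):
            if k == "M":
                s = rng.uniform(0.5, 20.0)
                params[k] = bp.BetaParams(s, s)
            else:
                params[k] = bp.BetaParams(rng.uniform(0.2, 30.0), rng.uniform(0.2, 30.0))
        emissions[a] = bp.ClassEmissions(a, params)
    pair_models = {}
    for pc in bp.PAIR_CLASSES:
        n1 = len(bp.allowed_states(pc[0]))
        n2 = len(bp.allowed_states(pc[1]))
        omega = rng.dirichlet(np.ones(n1))
        T = rng.dirichlet(np.ones(n2), size=n1)
        pair_models[pc] = bp.PairClassModel(pc, omega, T)
    return bp.SampleModel(sample_id, emissions, pair_models)


def brute_force_pair_density(x1: float, x2: float, pair_class: str, sm: bp.SampleModel) -> float:
    """Plain-float enumeration of the pair density over allowed joint states.

    Independent route: scipy.stats.beta.pdf in the probability domain with an
    explicit double loop, no shared code with the package's log-space path.
    """
    pm = sm.pair_models[pair_class]
    em1, em2 = sm.emissions_for_pair(pair_class)
    total = 0.0
    for i, k1 in enumerate(pm.states1):
        p1 = em1.params_by_state[k1]
        f1 = scipy.stats.beta.pdf(x1, p1.alpha, p1.beta)
        for j, k2 in enumerate(pm.states2):
            p2 = em2.params_by_state[k2]
            f2 = scipy.stats.beta.pdf(x2, p2.alpha, p2.beta)
            total += pm.omega_init[i] * pm.transition[i, j] * f1 * f2
    return total


def brute_force_posteriors(x1, x2, pair_class, sm):
    """Normalized enumeration of joint posteriors, probability domain."""
    pm = sm.pair_models[pair_class]
    em1, em2 = sm.emissions_for_pair(pair_class)
    raw = {}
    for i, k1 in enumerate(pm.states1):
        p1 = em1.params_by_state[k1]
        for j, k2 in enumerate(pm.states2):
            p2 = em2.params_by_state[k2]
            raw[(k1, k2)] = (
                pm.omega_init[i]
                * pm.transition[i, j]
                * scipy.stats.beta.pdf(x1, p1.alpha, p1.beta)
                * scipy.stats.beta.pdf(x2, p2.alpha, p2.beta)
            )
    z = sum(raw.values())
    return {k: v / z for k, v in raw.items()}


def uniform_model(sample_id: str = "uniform") -> bp.SampleModel:
    """All emissions Beta(1,1): the pair density is 1 everywhere."""
    emissions = {
        a: bp.ClassEmissions(
            a, {k: bp.BetaParams(1.0, 1.0) for k in bp.allowed_states(a)}
        )
        for a in bp.LOCATION_CLASSES
    }
    pair_models = {}
    rng = np.random.default_rng(7)
    for pc in bp.PAIR_CLASSES:
        n1 = len(bp.allowed_states(pc[0]))
        n2 = len(bp.allowed_states(pc[1]))
        pair_models[pc] = bp.PairClassModel(
            pc, rng.dirichlet(np.ones(n1)), rng.dirichlet(np.ones(n2), size=n1)
        )
    return bp.SampleModel(sample_id, emissions, pair_models)


@pytest.fixture(scope="session")
def normal_model():
    return bp.default_model("normal-like")


@pytest.fixture(scope="session")
def tumor_model():
    return bp.default_model("tumor-like")


@pytest.fixture(scope="session")
def small_simulated(normal_model):
    """A small simulated sample shared by fast tests: (betas, ann, truth)."""
    spec = bp.SimSpec(
        model=normal_model,
        n_pairs={"II": 400, "SS": 300, "OO": 300, "SI": 300},
        n_singletons={"I": 100, "S": 60, "O": 60},
        seed=11,
    )
    return bp.simulate_sample(spec)
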