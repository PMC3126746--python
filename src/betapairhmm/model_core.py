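"""Model types and exact density computations.

The generative model: a probe in location class ``a`` (CpG island ``I``,
shore ``S``, outside ``O``) occupies a hidden methylation state ``k`` in
{L, M, H} and emits a beta-value from Beta(alpha_ak, beta_ak).  The medium
state is symmetric (alpha == beta), and class ``I`` never reaches H (high
methylation is essentially absent inside islands), so the emission layer has
13 free shape parameters: 3 for I (2 for L, 1 for M) and 5 each for S and O.

The first two probes of a gene form a length-2 hidden Markov chain.  Pairs
are grouped by their ordered location classes into four modeled pair classes
(I,I), (S,S), (O,O) and (S,I); each class carries an initial state
distribution ``omega`` (7 free parameters over the four classes) and a
row-stochastic transition matrix ``T`` (17 free parameters), for 37 free
parameters per sample in total.

All densities are evaluated in natural-log space; joint sums use
log-sum-exp so that large beta shapes (alpha, beta > 100) do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import betaln, logsumexp

#: Canonical hidden-state order; used for indexing, tie-breaking and
#: serialization everywhere in the package.
STATES: tuple[str, ...] = ("L", "M", "H")

#: Probe location classes: inside a CpG island, island shore, outside.
LOCATION_CLASSES: tuple[str, ...] = ("I", "S", "O")

#: Modeled pair classes, keyed by the ordered classes of a gene's first two
#: probes.  (I,S) pairs are swapped into "SI" upstream; mixed pairs
#: involving O are excluded from pair modeling.
PAIR_CLASSES: tuple[str, ...] = ("II", "SS", "OO", "SI")

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}

_EPS = 1e-6  # clamp half-width for beta-values at the (0,1) boundary


class ModelError(ValueError):
    """Structural problem with model parameters or configuration."""


def allowed_states(location_class: str) -> tuple[str, ...]:
    """Hidden states reachable by a probe in the given location class.

    High methylation is structurally absent for island probes: the state is
    omitted from the model rather than carried with zero weight, which keeps
    both parameter counting and optimization well defined.
    """
    if location_class == "I":
        return ("L", "M")
    if location_class in ("S", "O"):
        return ("L", "M", "H")
    raise ModelError(f"unknown location class {location_class!r}")


def joint_states(pair_class: str) -> list[tuple[str, str]]:
    """Enumerate the allowed joint hidden states (k1, k2) of a pair class."""
    if pair_class not in PAIR_CLASSES:
        raise ModelError(f"unknown pair class {pair_class!r}")
    s1 = allowed_states(pair_class[0])
    s2 = allowed_states(pair_class[1])
    return [(k1, k2) for k1 in s1 for k2 in s2]


def state_sort_key(state: str) -> int:
    """Sort key implementing the canonical L < M < H order."""
    return _STATE_INDEX[state]


def clamp_beta_values(x, eps: float = _EPS):
    """Clamp beta-values into [eps, 1 - eps] before density evaluation.

    Exact 1.0 occurs on real arrays (fully methylated probes) and makes the
    density infinite whenever beta < 1; exact 0.0 entries are assumed to have
    been filtered as bad quality during preprocessing, but are clamped too as
    a safety net.
    """
    return np.clip(np.asarray(x, dtype=float), eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class BetaParams:
    """Shape pair of one beta emission distribution."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ModelError(
                f"beta shapes must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def is_symmetric(self, rtol: float = 1e-9) -> bool:
        return math.isclose(self.alpha, self.beta, rel_tol=rtol)


@dataclass(frozen=True)
class ClassEmissions:
    """Emission distributions of one location class, keyed by state.

    Class I holds two states (L, M); S and O hold three.  The medium state
    must be symmetric, so a class contributes 2 (L) + 1 (M) [+ 2 (H)] free
    shape parameters.
    """

    location_class: str
    params_by_state: Mapping[str, BetaParams]

    def __post_init__(self):
        expected = allowed_states(self.location_class)
        got = tuple(sorted(self.params_by_state, key=state_sort_key))
        if got != expected:
            raise ModelError(
                f"class {self.location_class} needs states {expected}, got {got}"
            )
        m = self.params_by_state["M"]
        if not m.is_symmetric():
            raise ModelError(
                f"medium state must be symmetric, got ({m.alpha}, {m.beta})"
            )

    @property
    def states(self) -> tuple[str, ...]:
        return allowed_states(self.location_class)

    def shape_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(alphas, betas) in canonical state order."""
        a = np.array([self.params_by_state[k].alpha for k in self.states])
        b = np.array([self.params_by_state[k].beta for k in self.states])
        return a, b

    def n_free_parameters(self) -> int:
        return sum(1 if k == "M" else 2 for k in self.states)


def _check_stochastic(vec: np.ndarray, what: str, atol: float = 1e-8) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if np.any(vec < -atol):
        raise ModelError(f"{what} has negative entries: {vec}")
    if not np.allclose(vec.sum(axis=-1), 1.0, atol=1e-6):
        raise ModelError(f"{what} rows must sum to 1, got sums {vec.sum(axis=-1)}")
    return np.clip(vec, 0.0, None)


@dataclass(frozen=True)
class PairClassModel:
    """Initial distribution and transition matrix of one pair class.

    ``omega_init`` is indexed by the allowed states of the first probe's
    location class; ``transition`` has one row per first-probe state and one
    column per second-probe state.  Free parameters: len(omega)-1 for the
    initial distribution and rows*(cols-1) for the transitions, i.e.
    (I,I): 1+2, (S,S)/(O,O): 2+6, (S,I): 2+3.
    """

    pair_class: str
    omega_init: np.ndarray
    transition: np.ndarray

    def __post_init__(self):
        if self.pair_class not in PAIR_CLASSES:
            raise ModelError(f"unknown pair class {self.pair_class!r}")
        n1 = len(allowed_states(self.pair_class[0]))
        n2 = len(allowed_states(self.pair_class[1]))
        omega = _check_stochastic(np.asarray(self.omega_init, float), "omega_init")
        if omega.shape != (n1,):
            raise ModelError(
                f"omega_init for {self.pair_class} must have length {n1}"
            )
        trans = np.asarray(self.transition, float)
        if trans.shape != (n1, n2):
            raise ModelError(
                f"transition for {self.pair_class} must be {n1}x{n2}, "
                f"got {trans.shape}"
            )
        trans = _check_stochastic(trans, f"transition[{self.pair_class}]")
        object.__setattr__(self, "omega_init", omega)
        object.__setattr__(self, "transition", trans)

    @property
    def states1(self) -> tuple[str, ...]:
        return allowed_states(self.pair_class[0])

    @property
    def states2(self) -> tuple[str, ...]:
        return allowed_states(self.pair_class[1])

    def joint_prior(self) -> np.ndarray:
        """omega[k1] * T[k1, k2]: the a priori joint-state distribution."""
        return self.omega_init[:, None] * self.transition

    def n_free_parameters(self) -> tuple[int, int]:
        """(initial-distribution, transition) free-parameter counts."""
        n1, n2 = self.transition.shape
        return n1 - 1, n1 * (n2 - 1)


@dataclass
class SampleModel:
    """One sample's full parameter set: emissions plus pair-class models."""

    sample_id: str
    emissions: dict[str, ClassEmissions]
    pair_models: dict[str, PairClassModel] = field(default_factory=dict)

    def __post_init__(self):
        for a, em in self.emissions.items():
            if em.location_class != a:
                raise ModelError(f"emissions key {a} holds class {em.location_class}")
        for pc, pm in self.pair_models.items():
            if pm.pair_class != pc:
                raise ModelError(f"pair_models key {pc} holds class {pm.pair_class}")
            for c in pc:
                if c not in self.emissions:
                    raise ModelError(
                        f"pair class {pc} requires emissions for class {c}"
                    )

    def emissions_for_pair(self, pair_class: str) -> tuple[ClassEmissions, ClassEmissions]:
        return self.emissions[pair_class[0]], self.emissions[pair_class[1]]


@dataclass(frozen=True)
class ProbePair:
    """Two beta-values of a gene's first two probes, plus their pair class."""

    gene_id: str
    x1: float
    x2: float
    pair_class: str

    def __post_init__(self):
        if self.pair_class not in PAIR_CLASSES:
            raise ModelError(f"unknown pair class {self.pair_class!r}")
        if not (0.0 < self.x1 < 1.0 and 0.0 < self.x2 < 1.0):
            raise ModelError(
                f"beta-values must lie strictly in (0,1), got "
                f"({self.x1}, {self.x2}); filter/clamp during preprocessing"
            )


# ---------------------------------------------------------------------------
# Densities


def log_beta_pdf(x, alpha, beta):
    """Vectorized natural-log beta density.

    Broadcasts over ``x`` and the shape parameters; callers are responsible
    for keeping x strictly inside (0,1) (see :func:`clamp_beta_values`).
    """
    x = np.asarray(x, dtype=float)
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    return (a - 1.0) * np.log(x) + (b - 1.0) * np.log1p(-x) - betaln(a, b)


def beta_log_density(x: float, p: BetaParams) -> float:
    """Log density of Beta(alpha, beta) at a single beta-value."""
    if not 0.0 < x < 1.0:
        raise ModelError(f"beta-value {x} outside (0,1)")
    return float(log_beta_pdf(x, p.alpha, p.beta))


def class_log_densities(x, em: ClassEmissions) -> np.ndarray:
    """Per-state log emission densities, shape (n, n_states)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    a, b = em.shape_arrays()
    return log_beta_pdf(x[:, None], a[None, :], b[None, :])


def single_mixture_density(x: float, em: ClassEmissions, omega) -> float:
    """Marginal beta-mixture density of one probe's beta-value.

    ``omega`` must be a probability vector over the class's allowed states
    in canonical order.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (len(em.states),):
        raise ModelError(
            f"omega length {omega.shape} does not match states {em.states}"
        )
    _check_stochastic(omega, "omega")
    if not 0.0 < x < 1.0:
        raise ModelError(f"beta-value {x} outside (0,1)")
    logf = class_log_densities(x, em)[0]
    with np.errstate(divide="ignore"):
        return float(np.exp(logsumexp(logf, b=omega)))


def pair_joint_log_density(x1, x2, pair_class: str, sm: SampleModel) -> np.ndarray:
    """Unnormalized joint log density over allowed joint states.

    Returns an array of shape (n, n1, n2) with entries
    ``log(omega[k1] T[k1,k2] f(x1;k1) f(x2;k2))`` for each pair; the
    log-sum-exp over the state axes is the pair log-likelihood and the
    softmax is the joint posterior.
    """
    if pair_class not in sm.pair_models:
        raise ModelError(f"no fitted model for pair class {pair_class!r}")
    pm = sm.pair_models[pair_class]
    em1, em2 = sm.emissions_for_pair(pair_class)
    logf1 = class_log_densities(x1, em1)  # (n, n1)
    logf2 = class_log_densities(x2, em2)  # (n, n2)
    with np.errstate(divide="ignore"):
        logw = np.log(pm.joint_prior())  # (n1, n2); -inf for zero prior
    return logw[None, :, :] + logf1[:, :, None] + logf2[:, None, :]


def pair_log_likelihood(pair: ProbePair, sm: SampleModel) -> float:
    """Log of the pair density: sum of omega*T*f1*f2 over allowed joint states."""
    lj = pair_joint_log_density(pair.x1, pair.x2, pair.pair_class, sm)
    return float(logsumexp(lj[0]))


# ---------------------------------------------------------------------------
# Free-parameter accounting


def count_free_parameters(sm: SampleModel) -> dict[str, int]:
    """Free-parameter breakdown under the symmetry and sum-to-one constraints.

    A fully specified model returns
    ``{"emission": 13, "mixture": 7, "transition": 17, "total": 37}``.
    """
    emission = sum(em.n_free_parameters() for em in sm.emissions.values())
    mixture = 0
    transition = 0
    for pm in sm.pair_models.values():
        n_omega, n_trans = pm.n_free_parameters()
        mixture += n_omega
        transition += n_trans
    return {
        "emission": emission,
        "mixture": mixture,
        "transition": transition,
        "total": emission + mixture + transition,
    }


# ---------------------------------------------------------------------------
# Serialization: flat key-value text, one parameter per line

_FLOAT_FMT = "%.17g"  # lossless for IEEE doubles


def model_to_records(sm: SampleModel) -> list[tuple[str, ...]]:
    """Flatten a model to (section, class, key..., value) string tuples."""
    rec: list[tuple[str, ...]] = [("sample_id", sm.sample_id)]
    for a in LOCATION_CLASSES:
        if a not in sm.emissions:
            continue
        em = sm.emissions[a]
        for k in em.states:
            p = em.params_by_state[k]
            rec.append(("emission", a, k, "alpha", _FLOAT_FMT % p.alpha))
            rec.append(("emission", a, k, "beta", _FLOAT_FMT % p.beta))
    for pc in PAIR_CLASSES:
        if pc not in sm.pair_models:
            continue
        pm = sm.pair_models[pc]
        for k, w in zip(pm.states1, pm.omega_init):
            rec.append(("omega", pc, k, _FLOAT_FMT % w))
        for i, k1 in enumerate(pm.states1):
            for j, k2 in enumerate(pm.states2):
                rec.append(("transition", pc, k1, k2, _FLOAT_FMT % pm.transition[i, j]))
    return rec


def model_from_records(records: Iterable[Sequence[str]]) -> SampleModel:
    sample_id = "sample"
    shapes: dict[str, dict[str, dict[str, float]]] = {}
    omegas: dict[str, dict[str, float]] = {}
    trans: dict[str, dict[tuple[str, str], float]] = {}
    for rec in records:
        kind = rec[0]
        if kind == "sample_id":
            sample_id = rec[1]
        elif kind == "emission":
            _, a, k, name, val = rec
            shapes.setdefault(a, {}).setdefault(k, {})[name] = float(val)
        elif kind == "omega":
            _, pc, k, val = rec
            omegas.setdefault(pc, {})[k] = float(val)
        elif kind == "transition":
            _, pc, k1, k2, val = rec
            trans.setdefault(pc, {})[(k1, k2)] = float(val)
        else:
            raise ModelError(f"unknown model record kind {kind!r}")
    emissions = {
        a: ClassEmissions(
            a,
            {k: BetaParams(d["alpha"], d["beta"]) for k, d in by_state.items()},
        )
        for a, by_state in shapes.items()
    }
    pair_models = {}
    for pc in omegas:
        s1 = allowed_states(pc[0])
        s2 = allowed_states(pc[1])
        omega = np.array([omegas[pc][k] for k in s1])
        T = np.array([[trans[pc][(k1, k2)] for k2 in s2] for k1 in s1])
        pair_models[pc] = PairClassModel(pc, omega, T)
    return SampleModel(sample_id, emissions, pair_models)


def save_model(sm: SampleModel, path, header_lines: Sequence[str] = ()) -> None:
    """Write a model to a flat tab-separated text file (one parameter per line)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for rec in model_to_records(sm):
            fh.write("\t".join(rec) + "\n")


def load_model(path) -> SampleModel:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            records.append(line.split("\t"))
    return model_from_records(records)
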