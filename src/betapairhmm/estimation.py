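"""Two-stage maximum-likelihood fitting of the per-sample model.

Stage 1 fits, for each location class (I, S, O), a beta mixture over the
hidden methylation states by EM: the E-step computes state responsibilities,
the M-step re-estimates the mixture proportions in closed form and the beta
shapes by numerical maximization of the expected complete-data
log-likelihood.  Because the weighted beta log-likelihood depends on the
data only through three sufficient statistics (sum of weights, weighted sums
of log x and log(1-x)), each shape update costs O(1) after the E-step
regardless of the number of probes.  The medium state is optimized over a
single shared shape (alpha == beta), never symmetrized after the fact.

Stage 2 holds the fitted emissions fixed and runs Baum-Welch on the
length-2 probe chains of each pair class: the E-step enumerates the joint
posterior over at most nine joint states exactly, and the M-step updates the
initial distribution and transition matrix in closed form.

Both stages are generalized EM procedures, so the observed-data
log-likelihood trace is non-decreasing (the shape update is guarded to never
accept a step that lowers the expected complete-data log-likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, digamma, logsumexp
from sklearn.base import BaseEstimator

from .model_core import (
    LOCATION_CLASSES,
    PAIR_CLASSES,
    BetaParams,
    ClassEmissions,
    ModelError,
    PairClassModel,
    ProbePair,
    SampleModel,
    allowed_states,
    clamp_beta_values,
    class_log_densities,
    count_free_parameters,
    log_beta_pdf,
)

_MONOTONE_SLACK = 1e-8  # numerical slack allowed on EM monotonicity


class DegenerateDataError(ValueError):
    """Raised when the data cannot identify a mixture (e.g. all values equal)."""


@dataclass
class FitConfig:
    """Optimization settings for both EM stages.

    Parameters
    ----------
    max_iter : maximum EM iterations per stage.
    tol : relative log-likelihood convergence threshold.
    shape_bounds : (low, high) box for the beta shapes; optimization runs on
        the log scale inside these bounds, which enforces positivity and
        keeps shapes away from degenerate boundary spikes.
    seed : seed for the restart perturbations.
    n_restarts : number of additional randomly perturbed EM starts for
        stage 1 (the default deterministic start splits values at 0.25/0.75
        into provisional L/M/H groups and initializes by method of moments).
    """

    max_iter: int = 500
    tol: float = 1e-8
    shape_bounds: tuple[float, float] = (0.01, 500.0)
    seed: int = 0
    n_restarts: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.shape_bounds[0] <= 0 or self.shape_bounds[1] <= self.shape_bounds[0]:
            raise ValueError("shape_bounds must satisfy 0 < low < high")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")


@dataclass
class FitResult:
    """Outcome of :func:`fit_sample`."""

    model: SampleModel
    loglik_trace: list[float]
    converged: bool
    n_iter: int
    traces: dict[str, list[float]] = field(default_factory=dict)
    marginal_omegas: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Weighted beta-shape maximum likelihood from sufficient statistics


def _weighted_beta_objective(a: float, b: float, W: float, S1: float, S2: float) -> float:
    return (a - 1.0) * S1 + (b - 1.0) * S2 - W * betaln(a, b)


def _optimize_shapes(
    start: tuple[float, float],
    W: float,
    S1: float,
    S2: float,
    bounds: tuple[float, float],
    symmetric: bool,
) -> tuple[float, float]:
    """Maximize the weighted beta log-likelihood over (alpha, beta).

    Works on log shapes with box bounds; for the symmetric medium state a
    single shared shape is optimized.  Returns the start point unless the
    optimizer strictly improves the objective (EM monotonicity guard).
    """
    if W <= 0:
        return start
    lo, hi = np.log(bounds[0]), np.log(bounds[1])

    if symmetric:
        s = S1 + S2

        def neg(u):
            a = np.exp(u[0])
            return -_weighted_beta_objective(a, a, W, S1, S2), np.array(
                [-(s - 2.0 * W * (digamma(a) - digamma(2.0 * a))) * a]
            )

        x0 = np.array([np.clip(np.log(start[0]), lo, hi)])
        res = minimize(neg, x0, jac=True, method="L-BFGS-B", bounds=[(lo, hi)])
        a = float(np.exp(res.x[0]))
        best = (a, a)
    else:

        def neg(u):
            a, b = np.exp(u)
            ga = S1 - W * (digamma(a) - digamma(a + b))
            gb = S2 - W * (digamma(b) - digamma(a + b))
            return (
                -_weighted_beta_objective(a, b, W, S1, S2),
                -np.array([ga * a, gb * b]),
            )

        x0 = np.clip(np.log(np.asarray(start)), lo, hi)
        res = minimize(neg, x0, jac=True, method="L-BFGS-B", bounds=[(lo, hi)] * 2)
        best = tuple(np.exp(res.x))

    f_start = _weighted_beta_objective(start[0], start[1], W, S1, S2)
    f_best = _weighted_beta_objective(best[0], best[1], W, S1, S2)
    return best if f_best > f_start else start


def _moment_shapes(values: np.ndarray, bounds: tuple[float, float]) -> tuple[float, float]:
    """Method-of-moments beta shapes, clipped into the bounds."""
    m = float(np.mean(values))
    v = float(np.var(values))
    if v <= 0:
        v = 1e-4
    c = m * (1.0 - m) / v - 1.0
    if c <= 0:
        c = 1.0
    a = np.clip(m * c, *bounds)
    b = np.clip((1.0 - m) * c, *bounds)
    return float(a), float(b)


def _symmetric_moment_shape(values: np.ndarray, bounds: tuple[float, float]) -> float:
    """Symmetric beta shape matched to the group variance (mean forced to 1/2)."""
    v = float(np.var(values)) if len(values) else 0.02
    v = min(max(v, 1e-4), 0.24)
    a = (1.0 / (4.0 * v) - 1.0) / 2.0
    return float(np.clip(a, *bounds))


_DEFAULT_SHAPES = {"L": (1.0, 9.0), "M": (5.0, 5.0), "H": (9.0, 1.0)}


def _initial_mixture(
    values: np.ndarray, states: tuple[str, ...], bounds: tuple[float, float]
) -> tuple[dict[str, tuple[float, float]], np.ndarray]:
    """Deterministic start: provisional L/M/H groups split at 0.25 and 0.75."""
    if "H" in states:
        groups = {
            "L": values[values < 0.25],
            "M": values[(values >= 0.25) & (values <= 0.75)],
            "H": values[values > 0.75],
        }
    else:
        groups = {"L": values[values < 0.25], "M": values[values >= 0.25]}
    shapes: dict[str, tuple[float, float]] = {}
    weights = []
    for k in states:
        g = groups[k]
        if len(g) >= 5:
            if k == "M":
                a = _symmetric_moment_shape(g, bounds)
                shapes[k] = (a, a)
            else:
                shapes[k] = _moment_shapes(g, bounds)
        else:
            shapes[k] = _DEFAULT_SHAPES[k]
        weights.append(len(g))
    omega = np.asarray(weights, float) + 0.5  # keep every state alive
    return shapes, omega / omega.sum()


def _run_mixture_em(
    x: np.ndarray,
    states: tuple[str, ...],
    shapes: dict[str, tuple[float, float]],
    omega: np.ndarray,
    cfg: FitConfig,
) -> tuple[dict[str, tuple[float, float]], np.ndarray, list[float], bool, int]:
    logx = np.log(x)
    log1mx = np.log1p(-x)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(cfg.max_iter):
        n_iter = it + 1
        a = np.array([shapes[k][0] for k in states])
        b = np.array([shapes[k][1] for k in states])
        logf = log_beta_pdf(x[:, None], a[None, :], b[None, :])
        with np.errstate(divide="ignore"):
            logj = logf + np.log(omega)[None, :]
        lse = logsumexp(logj, axis=1)
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logj - lse[:, None])

        omega = resp.mean(axis=0)
        new_shapes = {}
        for j, k in enumerate(states):
            W = float(resp[:, j].sum())
            S1 = float(resp[:, j] @ logx)
            S2 = float(resp[:, j] @ log1mx)
            new_shapes[k] = _optimize_shapes(
                shapes[k], W, S1, S2, cfg.shape_bounds, symmetric=(k == "M")
            )
        shapes = new_shapes

        if it > 0 and trace[-1] - trace[-2] < cfg.tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    return shapes, omega, trace, converged, n_iter


def fit_single_probe_mixture(
    values, location_class: str, cfg: FitConfig | None = None
) -> tuple[ClassEmissions, np.ndarray, list[float]]:
    """Fit the marginal beta mixture of one location class by EM.

    Returns the fitted emissions, the marginal mixture proportions over the
    class's allowed states (canonical order), and the per-iteration
    log-likelihood trace of the best start.
    """
    cfg = cfg or FitConfig()
    x = clamp_beta_values(np.asarray(values, dtype=float))
    x = x[~np.isnan(x)]
    if len(x) == 0:
        raise DegenerateDataError("no values to fit")
    if np.ptp(x) == 0:
        raise DegenerateDataError("all values identical; mixture not identifiable")
    if len(x) < 50:
        warnings.warn(
            f"only {len(x)} values for class {location_class}; "
            "mixture estimates will be unstable",
            stacklevel=2,
        )
    states = allowed_states(location_class)
    shapes0, omega0 = _initial_mixture(x, states, cfg.shape_bounds)

    starts = [(shapes0, omega0)]
    rng = np.random.default_rng(cfg.seed)
    for _ in range(cfg.n_restarts):
        shapes_r = {
            k: tuple(
                np.clip(np.asarray(v) * np.exp(rng.normal(0, 0.3, 2)), *cfg.shape_bounds)
            )
            for k, v in shapes0.items()
        }
        for k in shapes_r:  # keep the medium state symmetric
            if k == "M":
                shapes_r[k] = (shapes_r[k][0], shapes_r[k][0])
        omega_r = rng.dirichlet(10.0 * omega0 + 0.5)
        starts.append((shapes_r, omega_r))

    best = None
    for shapes_s, omega_s in starts:
        fit = _run_mixture_em(x, states, dict(shapes_s), np.asarray(omega_s), cfg)
        if best is None or fit[2][-1] > best[2][-1]:
            best = fit
    shapes, omega, trace, converged, _ = best
    if not converged:
        warnings.warn(
            f"stage-1 EM for class {location_class} did not converge in "
            f"{cfg.max_iter} iterations",
            stacklevel=2,
        )
    em = ClassEmissions(
        location_class, {k: BetaParams(*shapes[k]) for k in states}
    )
    return em, omega, trace


# ---------------------------------------------------------------------------
# Stage 2: Baum-Welch on length-2 chains, emissions fixed


def _fit_pair_hmm_arrays(
    x1: np.ndarray,
    x2: np.ndarray,
    pair_class: str,
    em1: ClassEmissions,
    em2: ClassEmissions,
    cfg: FitConfig,
    omega_start: np.ndarray | None = None,
) -> tuple[PairClassModel, list[float], bool, int]:
    n1, n2 = len(em1.states), len(em2.states)
    logf1 = class_log_densities(x1, em1)  # (n, n1)
    logf2 = class_log_densities(x2, em2)  # (n, n2)
    n = len(x1)

    omega = (
        np.full(n1, 1.0 / n1) if omega_start is None else np.asarray(omega_start, float)
    )
    T = np.full((n1, n2), 1.0 / n2)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(cfg.max_iter):
        n_iter = it + 1
        with np.errstate(divide="ignore"):
            logw = np.log(omega[:, None] * T)
        logj = logw[None, :, :] + logf1[:, :, None] + logf2[:, None, :]
        lse = logsumexp(logj, axis=(1, 2))
        ll = float(lse.sum())
        trace.append(ll)
        post = np.exp(logj - lse[:, None, None])  # (n, n1, n2)

        gamma1 = post.sum(axis=2)  # (n, n1) first-probe marginals
        omega = gamma1.sum(axis=0) / n
        num = post.sum(axis=0)  # (n1, n2)
        denom = gamma1.sum(axis=0)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            T = np.where(denom > 0, num / denom, 1.0 / n2)

        if it > 0 and trace[-1] - trace[-2] < cfg.tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    pm = PairClassModel(pair_class, omega, T)
    return pm, trace, converged, n_iter


def fit_pair_hmm(
    pairs: list[ProbePair],
    em1: ClassEmissions,
    em2: ClassEmissions,
    cfg: FitConfig | None = None,
    omega_start: np.ndarray | None = None,
) -> PairClassModel:
    """Baum-Welch estimation of one pair class's (omega, T), emissions fixed.

    All pairs must belong to a single pair class whose location classes match
    ``em1`` and ``em2``.
    """
    cfg = cfg or FitConfig()
    if not pairs:
        raise ValueError("empty pair list")
    pair_class = pairs[0].pair_class
    if any(p.pair_class != pair_class for p in pairs):
        raise ModelError("all pairs must share one pair class")
    if em1.location_class != pair_class[0] or em2.location_class != pair_class[1]:
        raise ModelError(
            f"emission classes ({em1.location_class},{em2.location_class}) "
            f"do not match pair class {pair_class}"
        )
    if len(pairs) < 50:
        warnings.warn(
            f"only {len(pairs)} pairs for class {pair_class}; "
            "transition estimates will be unstable",
            stacklevel=2,
        )
    x1 = clamp_beta_values([p.x1 for p in pairs])
    x2 = clamp_beta_values([p.x2 for p in pairs])
    pm, _, _, _ = _fit_pair_hmm_arrays(x1, x2, pair_class, em1, em2, cfg, omega_start)
    return pm


# ---------------------------------------------------------------------------
# Full-sample orchestration


_REQUIRED_COLS = ("gene_id", "location_class", "position", "beta")


def pairs_from_probe_table(probes: pd.DataFrame) -> list[ProbePair]:
    """Assemble modeled probe pairs from a per-sample probe table.

    Per gene, probes are ordered by genomic position and the first two are
    taken; the pair class is the ordered location classes, with (I,S)
    swapped into (S,I) (values swapped too); mixed pairs involving O and
    pairs with a missing beta-value are dropped.
    """
    for c in _REQUIRED_COLS:
        if c not in probes.columns:
            raise ValueError(f"probe table lacks required column {c!r}")
    pairs: list[ProbePair] = []
    df = probes.sort_values(["gene_id", "position"], kind="mergesort")
    for gene_id, grp in df.groupby("gene_id", sort=True):
        if len(grp) < 2:
            continue
        first = grp.iloc[0]
        second = grp.iloc[1]
        if pd.isna(first["beta"]) or pd.isna(second["beta"]):
            continue
        c1, c2 = first["location_class"], second["location_class"]
        x1, x2 = float(first["beta"]), float(second["beta"])
        if c1 == "I" and c2 == "S":
            c1, c2, x1, x2 = c2, c1, x2, x1
        pc = c1 + c2
        if pc not in PAIR_CLASSES:
            continue
        x1, x2 = float(clamp_beta_values(x1)), float(clamp_beta_values(x2))
        pairs.append(ProbePair(str(gene_id), x1, x2, pc))
    return pairs


def fit_sample(
    probes: pd.DataFrame,
    cfg: FitConfig | None = None,
    sample_id: str = "sample",
) -> FitResult:
    """Fit the full per-sample model from a preprocessed probe table.

    ``probes`` holds one sample: columns gene_id, location_class, position,
    beta (NaN for filtered probes).  Stage 1 pools all probes of a location
    class — including probes of unpaired genes, since the marginal mixture
    applies to single probes too.  Stage 2 fits each pair class present,
    initializing its initial-state distribution at the stage-1 marginal of
    the first probe's class.  Classes with no data are omitted (with a
    warning), shrinking the free-parameter count accordingly.
    """
    cfg = cfg or FitConfig()
    for c in _REQUIRED_COLS:
        if c not in probes.columns:
            raise ValueError(f"probe table lacks required column {c!r}")

    emissions: dict[str, ClassEmissions] = {}
    marginal_omegas: dict[str, np.ndarray] = {}
    traces: dict[str, list[float]] = {}
    converged = True
    n_iter = 0
    for a in LOCATION_CLASSES:
        vals = probes.loc[probes["location_class"] == a, "beta"].dropna().to_numpy()
        if len(vals) == 0:
            warnings.warn(f"no probes in location class {a}; class omitted")
            continue
        em, omega, trace = fit_single_probe_mixture(vals, a, cfg)
        emissions[a] = em
        marginal_omegas[a] = omega
        traces[f"stage1:{a}"] = trace
        n_iter += len(trace)

    pairs = pairs_from_probe_table(probes)
    by_class: dict[str, list[ProbePair]] = {}
    for p in pairs:
        by_class.setdefault(p.pair_class, []).append(p)

    pair_models: dict[str, PairClassModel] = {}
    for pc in PAIR_CLASSES:
        plist = by_class.get(pc, [])
        if not plist:
            warnings.warn(f"no probe pairs in class {pc}; class omitted")
            continue
        if pc[0] not in emissions or pc[1] not in emissions:
            warnings.warn(f"pair class {pc} lacks fitted emissions; class omitted")
            continue
        x1 = clamp_beta_values([p.x1 for p in plist])
        x2 = clamp_beta_values([p.x2 for p in plist])
        pm, trace, conv, it = _fit_pair_hmm_arrays(
            x1,
            x2,
            pc,
            emissions[pc[0]],
            emissions[pc[1]],
            cfg,
            omega_start=marginal_omegas[pc[0]],
        )
        pair_models[pc] = pm
        traces[f"stage2:{pc}"] = trace
        converged &= conv
        n_iter += it

    model = SampleModel(sample_id, emissions, pair_models)
    flat = [v for key in sorted(traces) for v in traces[key]]
    return FitResult(
        model=model,
        loglik_trace=flat,
        converged=converged,
        n_iter=n_iter,
        traces=traces,
        marginal_omegas=marginal_omegas,
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator


class BetaPairHMM(BaseEstimator):
    """Beta-mixture pair HMM of one methylation sample, sklearn style.

    ``fit`` takes a per-sample probe table (columns gene_id, location_class,
    position, beta) and estimates the 37-parameter model in the two stages
    described in this module.  ``predict`` returns Viterbi joint states for
    probe pairs, ``predict_proba`` their exact joint posteriors, and
    ``score`` the mean pair log-likelihood.

    Parameters mirror :class:`FitConfig`.

    Attributes
    ----------
    model_ : SampleModel
        The fitted parameter set.
    result_ : FitResult
        Full fit diagnostics (traces, convergence flags).
    n_parameters_ : int
        Total free parameters of the fitted model (37 when all four pair
        classes are present).
    """

    def __init__(
        self,
        max_iter: int = 500,
        tol: float = 1e-8,
        shape_bounds: tuple[float, float] = (0.01, 500.0),
        seed: int = 0,
        n_restarts: int = 0,
        sample_id: str = "sample",
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.shape_bounds = shape_bounds
        self.seed = seed
        self.n_restarts = n_restarts
        self.sample_id = sample_id

    def _config(self) -> FitConfig:
        return FitConfig(
            max_iter=self.max_iter,
            tol=self.tol,
            shape_bounds=tuple(self.shape_bounds),
            seed=self.seed,
            n_restarts=self.n_restarts,
        )

    def fit(self, X: pd.DataFrame, y=None):
        result = fit_sample(X, self._config(), sample_id=self.sample_id)
        self.result_ = result
        self.model_ = result.model
        self.converged_ = result.converged
        self.loglik_trace_ = result.loglik_trace
        self.n_parameters_ = count_free_parameters(result.model)["total"]
        return self

    def _as_pairs(self, X) -> list[ProbePair]:
        if isinstance(X, pd.DataFrame):
            if {"x1", "x2", "pair_class"}.issubset(X.columns):
                gene = X["gene_id"] if "gene_id" in X.columns else X.index.astype(str)
                return [
                    ProbePair(str(g), float(r.x1), float(r.x2), r.pair_class)
                    for g, r in zip(gene, X.itertuples())
                ]
            return pairs_from_probe_table(X)
        return list(X)

    def predict(self, X):
        """Viterbi (MAP) joint state per probe pair, as 'LM'-style strings."""
        from .inference import viterbi_pair

        return np.array(
            ["".join(viterbi_pair(p, self.model_)) for p in self._as_pairs(X)]
        )

    def predict_proba(self, X):
        """Exact joint posteriors, one :class:`PairPosterior` per pair."""
        from .inference import pair_posteriors

        return [pair_posteriors(p, self.model_) for p in self._as_pairs(X)]

    def score(self, X, y=None) -> float:
        """Mean pair log-likelihood under the fitted model."""
        from .model_core import pair_log_likelihood

        pairs = self._as_pairs(X)
        return float(np.mean([pair_log_likelihood(p, self.model_) for p in pairs]))
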