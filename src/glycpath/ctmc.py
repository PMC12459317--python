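"""Continuous-time Markov chain machinery for panel-observed disease states.

The chain lives on a small ordered state space (here typically
``NORMO -> prediabetes -> DM``) and is parameterised by a transition-intensity
(generator) matrix ``Q`` in units of 1/year: off-diagonal ``q_ij >= 0`` is the
instantaneous rate of moving from state ``i`` to state ``j``, rows sum to
zero, and absorbing states have identically-zero rows.  Panel observation
means the state is only seen at visit times, so the likelihood of an interval
``(from, to, dt)`` is the matrix-exponential transition probability
``P_{from,to}(dt)`` with ``P(t) = expm(Q t)``.

This module provides the generator/probability algebra, the panel
log-likelihood, maximum-likelihood fitting on log-intensities, and the
functionals the natural-history analysis reports: annual transition
probabilities (ATP, entries of ``P(1)`` in percent), mean single-stay sojourn
times ``-1/q_ii``, and expected total length of residence in each transient
state before absorption, taken from the fundamental matrix
``(-Q_TT)^{-1}``.  Confidence intervals for all functionals come from normal
simulation on the fitted log-intensities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, logm
from scipy.optimize import minimize

__all__ = [
    "CtmcStructure",
    "IntervalCounts",
    "FitResult",
    "validate_generator",
    "build_generator",
    "transition_matrix",
    "panel_loglik",
    "fit_ctmc",
    "annual_transitions",
    "mean_sojourn",
    "total_length_of_stay",
    "residence_estimate",
    "generator_from_annual",
]

# Numerical policy (shared across the package)
ROW_SUM_TOL = 1e-10
EMBED_CLIP = 1e-8           # off-diagonal logm entries above -EMBED_CLIP are clipped to 0
THETA_LOWER = -12.0         # log-intensity box: exp(-12) / year ~ one event per 160 ky
THETA_UPPER = 3.0
GRAD_TOL = 1e-8
LOGLIK_FLOOR = 1e-300       # probability clip inside the optimiser objective


class NotEmbeddableError(ValueError):
    """A stochastic matrix has no valid generator (principal log fails)."""


@dataclass(frozen=True)
class CtmcStructure:
    """State space, absorbing flags and allowed off-diagonal transitions.

    ``allowed`` lists the (from, to) index pairs whose intensity is a free
    parameter; every other off-diagonal intensity is structurally zero.
    """

    states: tuple[str, ...]
    absorbing: frozenset[str]
    allowed: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        idx = {s: i for i, s in enumerate(self.states)}
        if len(idx) != len(self.states):
            raise ValueError("duplicate state labels")
        for a in self.absorbing:
            if a not in idx:
                raise ValueError(f"absorbing state {a!r} not in state space")
        for i, j in self.allowed:
            if i == j:
                raise ValueError("diagonal entries are not free parameters")
            if self.states[i] in self.absorbing:
                raise ValueError("absorbing states cannot have outgoing transitions")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self.states.index(state)

    @property
    def transient_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if s not in self.absorbing]


@dataclass
class IntervalCounts:
    """Aggregated panel transitions: (from-state, to-state, elapsed years) -> count.

    The mapping is the sufficient statistic of the panel likelihood for a
    homogeneous chain: every consecutive observed visit pair contributes one
    count, and the total count equals the number of contributing pairs.
    """

    cells: dict[tuple[str, str, float], float] = field(default_factory=dict)

    def add(self, from_state: str, to_state: str, dt: float, count: float = 1) -> None:
        if dt <= 0:
            raise ValueError(f"interval length must be positive, got {dt}")
        key = (from_state, to_state, float(dt))
        self.cells[key] = self.cells.get(key, 0) + count

    @property
    def total(self) -> float:
        return sum(self.cells.values())

    def pair_totals(self) -> dict[tuple[str, str], float]:
        """Counts summed over interval lengths, keyed by (from, to)."""
        out: dict[tuple[str, str], float] = {}
        for (a, b, _dt), c in self.cells.items():
            out[(a, b)] = out.get((a, b), 0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"from": a, "to": b, "dt_years": dt, "count": c}
            for (a, b, dt), c in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["from", "to", "dt_years", "count"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalCounts":
        ic = cls()
        for row in df.itertuples(index=False):
            ic.add(str(row[0]), str(row[1]), float(row[2]), float(row[3]))
        return ic


@dataclass
class FitResult:
    """Maximum-likelihood fit of the intensities of a panel-observed CTMC."""

    structure: CtmcStructure
    theta: np.ndarray              # log-intensities, one per allowed transition
    q_hat: np.ndarray
    cov_theta: np.ndarray
    loglik: float
    converged: bool
    n_intervals: float
    pair_counts: dict[tuple[str, str], float] = field(default_factory=dict)
    n_dropped: int = 0             # pairs inadmissible under the structure
    messages: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "states": list(self.structure.states),
            "absorbing": sorted(self.structure.absorbing),
            "allowed": [list(p) for p in self.structure.allowed],
            "theta": self.theta.tolist(),
            "Q": self.q_hat.tolist(),
            "cov_theta": self.cov_theta.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_intervals": self.n_intervals,
            "pair_counts": {f"{a}->{b}": c for (a, b), c in sorted(self.pair_counts.items())},
            "n_dropped": self.n_dropped,
            "messages": self.messages,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        structure = CtmcStructure(
            states=tuple(d["states"]),
            absorbing=frozenset(d["absorbing"]),
            allowed=tuple((int(i), int(j)) for i, j in d["allowed"]),
        )
        pair_counts = {}
        for key, c in d.get("pair_counts", {}).items():
            a, b = key.split("->")
            pair_counts[(a, b)] = c
        return cls(
            structure=structure,
            theta=np.asarray(d["theta"], dtype=float),
            q_hat=np.asarray(d["Q"], dtype=float),
            cov_theta=np.asarray(d["cov_theta"], dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n_intervals=float(d["n_intervals"]),
            pair_counts=pair_counts,
            n_dropped=int(d.get("n_dropped", 0)),
            messages=list(d.get("messages", [])),
        )


def validate_generator(
    q: np.ndarray,
    absorbing: Iterable[int] = (),
    allowed: Sequence[tuple[int, int]] | None = None,
    tol: float = ROW_SUM_TOL,
) -> np.ndarray:
    """Check generator invariants and return the matrix as a float array.

    Off-diagonals must be non-negative, rows must sum to zero (within *tol*),
    absorbing rows must be identically zero, and — when an allowed-transition
    mask is given — disallowed off-diagonals must be exactly zero.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("generator must be a square matrix")
    n = q.shape[0]
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal intensities must be non-negative")
    if np.any(np.abs(q.sum(axis=1)) > tol):
        raise ValueError("generator rows must sum to zero")
    absorbing = set(absorbing)
    for i in absorbing:
        if np.any(q[i] != 0):
            raise ValueError(f"absorbing row {i} must be identically zero")
    if allowed is not None:
        mask = np.zeros((n, n), dtype=bool)
        for i, j in allowed:
            mask[i, j] = True
        if np.any(off[~mask] != 0):
            raise ValueError("disallowed transitions must have zero intensity")
    return q


def build_generator(structure: CtmcStructure, theta: np.ndarray) -> np.ndarray:
    """Assemble Q from log-intensities over the allowed transitions."""
    n = structure.n_states
    q = np.zeros((n, n))
    for value, (i, j) in zip(np.exp(np.asarray(theta, dtype=float)), structure.allowed):
        q[i, j] = value
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """Transition probabilities P(t) = expm(Q t) for elapsed time t >= 0 years."""
    if t < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t}")
    q = np.asarray(q, dtype=float)
    if t == 0:
        return np.eye(q.shape[0])
    p = expm(q * t)
    # expm of a valid generator is stochastic up to roundoff; tidy the noise
    p = np.clip(p, 0.0, None)
    return p


def panel_loglik(q: np.ndarray, data: IntervalCounts, structure: CtmcStructure) -> float:
    """Panel-data log-likelihood: sum of count * log P_{from,to}(dt).

    Returns ``-inf`` when any observed cell has probability zero under ``q``
    (e.g. a regression observed under a unidirectional model).
    """
    idx = {s: i for i, s in enumerate(structure.states)}
    by_dt: dict[float, list[tuple[int, int, float]]] = {}
    for (a, b, dt), c in data.cells.items():
        if a not in idx or b not in idx:
            raise ValueError(f"state outside the model space: {a!r} or {b!r}")
        if structure.states.index(a) not in structure.transient_indices:
            raise ValueError(f"interval starting in absorbing state {a!r}")
        by_dt.setdefault(dt, []).append((idx[a], idx[b], c))
    total = 0.0
    for dt, cells in by_dt.items():
        p = transition_matrix(q, dt)
        for i, j, c in cells:
            pij = p[i, j]
            if pij <= 0:
                return -np.inf
            total += c * np.log(pij)
    return total


def _crude_rates(structure: CtmcStructure, data: IntervalCounts) -> np.ndarray:
    """Initial log-intensities from observed counts / approximate person-time.

    Person-time at risk in state i is approximated by the total length of
    intervals that start in i; empty transitions fall back to a small rate.
    """
    person_time = {s: 0.0 for s in structure.states}
    counts = {}
    for (a, b, dt), c in data.cells.items():
        person_time[a] += c * dt
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + c
    theta0 = np.empty(len(structure.allowed))
    for k, (i, j) in enumerate(structure.allowed):
        a, b = structure.states[i], structure.states[j]
        pt = person_time.get(a, 0.0)
        rate = counts.get((a, b), 0.0) / pt if pt > 0 else 0.0
        theta0[k] = np.log(rate) if rate > 0 else np.log(1e-3)
    return theta0


def _numerical_hessian(fun, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = x.size
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return hess


def fit_ctmc(
    structure: CtmcStructure,
    data: IntervalCounts,
    n_starts: int = 3,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the transition intensities from panel counts.

    Optimises the panel log-likelihood over log-intensities (positivity by
    construction) with L-BFGS-B from multiple starts: crude-rate initial
    values, then the same scaled by 0.5 and 2.  The covariance of the
    log-intensities is the inverse of the numerically estimated curvature of
    the negative log-likelihood at the optimum.
    """
    if not data.cells:
        raise ValueError("no interval data to fit")
    from_states = {a for (a, b, dt) in data.cells}
    for i, j in structure.allowed:
        if structure.states[i] not in from_states:
            raise ValueError(
                f"allowed transition from {structure.states[i]!r} but that state "
                "never appears as a from-state in the data"
            )

    idx = {s: i for i, s in enumerate(structure.states)}
    by_dt: dict[float, list[tuple[int, int, float]]] = {}
    for (a, b, dt), c in data.cells.items():
        if a not in idx or b not in idx:
            raise ValueError(f"state outside the model space: {a!r}/{b!r}")
        by_dt.setdefault(dt, []).append((idx[a], idx[b], c))

    def negloglik(theta: np.ndarray) -> float:
        q = build_generator(structure, theta)
        total = 0.0
        for dt, cells in by_dt.items():
            p = transition_matrix(q, dt)
            for i, j, c in cells:
                total -= c * np.log(max(p[i, j], LOGLIK_FLOOR))
        return total

    base = _crude_rates(structure, data) if theta0 is None else np.asarray(theta0, float)
    scales = [0.0, np.log(0.5), np.log(2.0)][:max(1, n_starts)]
    best = None
    messages: list[str] = []
    bounds = [(THETA_LOWER, THETA_UPPER)] * len(structure.allowed)
    for s in scales:
        res = minimize(
            negloglik,
            np.clip(base + s, THETA_LOWER, THETA_UPPER),
            method="L-BFGS-B",
            bounds=bounds,
            options={"gtol": GRAD_TOL, "ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta_hat = np.asarray(best.x, dtype=float)
    converged = bool(best.success)
    if not converged:
        messages.append(f"optimizer did not converge: {best.message}")
    at_lower = theta_hat <= THETA_LOWER + 1e-6
    if np.any(at_lower):
        for k in np.where(at_lower)[0]:
            i, j = structure.allowed[k]
            msg = (
                f"intensity {structure.states[i]}->{structure.states[j]} driven to "
                "its lower bound (transition effectively unobserved)"
            )
            messages.append(msg)
            warnings.warn(msg, stacklevel=2)

    hess = _numerical_hessian(negloglik, theta_hat)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        messages.append("singular curvature matrix; pseudo-inverse covariance")
    cov = (cov + cov.T) / 2
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8:
        # project onto the PSD cone so downstream normal simulation is defined
        w, v = np.linalg.eigh(cov)
        cov = (v * np.clip(w, 0.0, None)) @ v.T
        messages.append("covariance projected to positive semidefinite")

    q_hat = build_generator(structure, theta_hat)
    return FitResult(
        structure=structure,
        theta=theta_hat,
        q_hat=q_hat,
        cov_theta=cov,
        loglik=-best.fun,
        converged=converged,
        n_intervals=data.total,
        pair_counts=data.pair_totals(),
        messages=messages,
    )


def _draw_generators(fit: FitResult, b: int, rng: np.random.Generator) -> np.ndarray:
    """B generator draws via theta ~ Normal(theta_hat, cov_theta)."""
    thetas = rng.multivariate_normal(fit.theta, fit.cov_theta, size=b)
    return np.stack([build_generator(fit.structure, th) for th in thetas])


def annual_transitions(
    fit: FitResult,
    b: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Annual transition probability table: 100 x P(1) with percentile 95% CIs.

    One row per (from, to) pair with the from-state transient, mirroring the
    published table layout ``from, to, n, atp_pct, ci_lo, ci_hi``; ``n`` is
    the observed interval count for the pair.  CIs come from *b* normal
    draws of the log-intensities pushed through exp -> Q -> P(1).
    """
    if b < 100:
        warnings.warn(f"B={b} draws is too few for stable percentile CIs", stacklevel=2)
    rng = np.random.default_rng(rng)
    structure = fit.structure
    p1 = transition_matrix(fit.q_hat, 1.0)
    flagged = False
    if np.allclose(fit.cov_theta, 0):
        draws = np.repeat(p1[None, :, :], max(b, 1), axis=0)
    else:
        try:
            qs = _draw_generators(fit, b, rng)
            draws = np.stack([transition_matrix(q, 1.0) for q in qs])
        except np.linalg.LinAlgError:
            draws = np.repeat(p1[None, :, :], max(b, 1), axis=0)
            flagged = True
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    rows = []
    for i in structure.transient_indices:
        for j in range(structure.n_states):
            rows.append({
                "from": structure.states[i],
                "to": structure.states[j],
                "n": fit.pair_counts.get((structure.states[i], structure.states[j]), 0),
                "atp_pct": 100 * p1[i, j],
                "ci_lo": 100 * lo[i, j],
                "ci_hi": 100 * hi[i, j],
                "ci_flagged": flagged,
            })
    return pd.DataFrame(rows)


def mean_sojourn(q: np.ndarray, absorbing: Iterable[int] = ()) -> np.ndarray:
    """Mean single-stay sojourn time -1/q_ii per state; inf for absorbing states."""
    q = np.asarray(q, dtype=float)
    absorbing = set(absorbing)
    out = np.empty(q.shape[0])
    for i in range(q.shape[0]):
        if i in absorbing:
            out[i] = np.inf
        elif q[i, i] >= 0:
            raise ValueError(f"non-absorbing state {i} has q_ii = {q[i, i]} >= 0")
        else:
            out[i] = -1.0 / q[i, i]
    return out


def total_length_of_stay(
    q: np.ndarray,
    start: int,
    absorbing: Iterable[int],
) -> dict[int, float]:
    """Expected total years in each transient state before absorption.

    Row ``start`` of the fundamental matrix ``(-Q_TT)^{-1}``, which equals the
    time integral of ``P_{start,j}(t)`` over all t for transient j.
    """
    q = np.asarray(q, dtype=float)
    absorbing = set(absorbing)
    transient = [i for i in range(q.shape[0]) if i not in absorbing]
    if start not in transient:
        raise ValueError("start state must be transient")
    qtt = q[np.ix_(transient, transient)]
    try:
        fundamental = np.linalg.inv(-qtt)
    except np.linalg.LinAlgError as exc:
        raise ValueError("absorption unreachable: transient block is singular") from exc
    row = fundamental[transient.index(start)]
    return {j: row[k] for k, j in enumerate(transient)}


def residence_estimate(
    fit: FitResult,
    start_state: str = "NORMO",
    b: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Total length of residence per transient state with simulation CIs.

    Conditional on starting in ``start_state``; the same normal-simulation
    transform as :func:`annual_transitions` provides the percentile CIs.
    """
    rng = np.random.default_rng(rng)
    structure = fit.structure
    absorbing_idx = [structure.index(s) for s in structure.absorbing]
    start = structure.index(start_state)
    point = total_length_of_stay(fit.q_hat, start, absorbing_idx)
    if np.allclose(fit.cov_theta, 0):
        draws = {j: np.full(max(b, 1), point[j]) for j in point}
    else:
        qs = _draw_generators(fit, b, rng)
        draws = {j: np.empty(len(qs)) for j in point}
        for k, qd in enumerate(qs):
            res = total_length_of_stay(qd, start, absorbing_idx)
            for j in point:
                draws[j][k] = res[j]
    rows = []
    for j, value in point.items():
        rows.append({
            "state": structure.states[j],
            "years": value,
            "ci_lo": float(np.percentile(draws[j], 2.5)),
            "ci_hi": float(np.percentile(draws[j], 97.5)),
            "start_state": start_state,
        })
    return pd.DataFrame(rows)


def generator_from_annual(p1: np.ndarray) -> np.ndarray:
    """Map a one-year stochastic matrix to its generator by principal matrix log.

    Validates embeddability: eigenvalues must be real and positive, the
    principal log's off-diagonals must be >= -1e-8 (tiny negatives from input
    rounding are clipped to zero and rows re-zeroed), and ``expm`` of the
    result must reproduce the input to 1e-8.
    """
    p1 = np.asarray(p1, dtype=float)
    if p1.ndim != 2 or p1.shape[0] != p1.shape[1]:
        raise NotEmbeddableError("annual matrix must be square")
    if np.any(np.abs(p1.sum(axis=1) - 1) > 1e-8):
        raise NotEmbeddableError("annual matrix rows must sum to 1")
    eig = np.linalg.eigvals(p1)
    if np.any(np.abs(eig.imag) > 1e-10) or np.any(eig.real <= 0):
        raise NotEmbeddableError(
            f"annual matrix has complex or non-positive eigenvalues: {eig}"
        )
    q = logm(p1)
    if np.any(np.abs(q.imag) > 1e-10):
        raise NotEmbeddableError("principal matrix logarithm is not real")
    q = q.real
    off = q - np.diag(np.diag(q))
    if np.any(off < -EMBED_CLIP):
        raise NotEmbeddableError(
            f"matrix log has negative off-diagonal intensities below -{EMBED_CLIP}"
        )
    q[(off < 0) & ~np.eye(q.shape[0], dtype=bool)] = 0.0
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if np.max(np.abs(transition_matrix(q, 1.0) - p1)) > 1e-8:
        raise NotEmbeddableError("clipped generator does not reproduce the annual matrix")
    return q
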