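"""Multistate processes with multiplicative piecewise-constant intensities.

A process ``Z(t)`` on states ``0..K-1`` moves between states ``k -> r``
with intensity

    lambda_kr(t | V) = lambda_kr0(t) * exp(x_kr(V)' beta_kr),

where the baseline ``lambda_kr0`` is constant on the pieces of a common
cut-point grid and the multiplier is log-linear in covariates (and,
for joint models whose state encodes markers/treatment, in indicator
terms read off the source state).  Transition-probability matrices over
an interval are products of matrix exponentials of the generator, one
per baseline piece.

Time is measured in years; the origin (disease onset, start of a
calendar window, ...) is a property of the data/configuration, not of
this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._expm import expm

__all__ = [
    "Term",
    "MultistateModelSpec",
    "ParameterVector",
    "CovariateError",
    "build_generator",
    "transition_probability",
    "state_entry_risk",
    "piece_index",
]


class CovariateError(KeyError):
    """A covariate required by the model design is missing."""


@dataclass(frozen=True)
class Term:
    """One additive term of a transition's log-linear multiplier.

    ``coef`` names the regression coefficient.  If ``covariate`` is set,
    the term contributes ``coef * scale * V[covariate]``; otherwise it
    contributes ``coef * scale`` — a constant regressor, used by joint-model
    builders for indicators (marker level, treatment status) that are a
    deterministic function of the source state.
    """

    coef: str
    covariate: str | None = None
    scale: float = 1.0


Transition = tuple[int, int]


@dataclass(frozen=True)
class MultistateModelSpec:
    """State space, allowed transitions, baseline pieces and designs.

    Parameters are *named*: each transition maps to a baseline family
    (transitions sharing a family share their piecewise log-baselines)
    and to a tuple of :class:`Term` s.  Distinct transitions may reuse a
    coefficient name, which is how joint-model builders tie parameters
    across structurally identical transitions.
    """

    n_states: int
    transitions: tuple[Transition, ...]
    absorbing: frozenset[int] = frozenset()
    cutpoints: tuple[float, ...] = ()
    baseline: Mapping[Transition, str] = field(default_factory=dict)
    design: Mapping[Transition, tuple[Term, ...]] = field(default_factory=dict)
    state_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("need at least one state")
        object.__setattr__(self, "transitions", tuple((int(k), int(r)) for k, r in self.transitions))
        object.__setattr__(self, "absorbing", frozenset(int(s) for s in self.absorbing))
        object.__setattr__(self, "cutpoints", tuple(float(c) for c in self.cutpoints))
        for k, r in self.transitions:
            if k == r:
                raise ValueError(f"self-transition {k}->{r} not allowed")
            if not (0 <= k < self.n_states and 0 <= r < self.n_states):
                raise ValueError(f"transition {k}->{r} outside state space")
            if k in self.absorbing:
                raise ValueError(f"transition {k}->{r} leaves absorbing state {k}")
        if len(set(self.transitions)) != len(self.transitions):
            raise ValueError("duplicate transitions")
        cps = self.cutpoints
        if any(c <= 0 for c in cps) or any(b <= a for a, b in zip(cps, cps[1:])):
            raise ValueError("cutpoints must be strictly increasing and positive")
        baseline = dict(self.baseline)
        for t in self.transitions:
            baseline.setdefault(t, f"q{t[0]}{t[1]}")
        extra = set(baseline) - set(self.transitions)
        if extra:
            raise ValueError(f"baseline families for unknown transitions: {sorted(extra)}")
        object.__setattr__(self, "baseline", baseline)
        design = {t: tuple(self.design.get(t, ())) for t in self.transitions}
        extra = set(self.design) - set(self.transitions)
        if extra:
            raise ValueError(f"designs for unknown transitions: {sorted(extra)}")
        object.__setattr__(self, "design", design)
        if self.state_names is not None and len(self.state_names) != self.n_states:
            raise ValueError("state_names length mismatch")

    # -- derived layout ------------------------------------------------

    @property
    def n_pieces(self) -> int:
        return len(self.cutpoints) + 1

    @property
    def baseline_families(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.transitions:
            seen.setdefault(self.baseline[t], None)
        return tuple(seen)

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.transitions:
            for term in self.design[t]:
                seen.setdefault(term.coef, None)
        return tuple(seen)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.transitions:
            for term in self.design[t]:
                if term.covariate is not None:
                    seen.setdefault(term.covariate, None)
        return tuple(seen)

    def parameter_names(self) -> tuple[str, ...]:
        """Flat parameter layout: baselines (family-major, piece-minor), then coefficients."""
        names = [f"log_{fam}[{j}]" for fam in self.baseline_families for j in range(self.n_pieces)]
        names.extend(self.coefficient_names)
        return tuple(names)

    def reachable(self, start: int) -> frozenset[int]:
        out: dict[int, list[int]] = {}
        for k, r in self.transitions:
            out.setdefault(k, []).append(r)
        seen = {start}
        stack = [start]
        while stack:
            for r in out.get(stack.pop(), ()):
                if r not in seen:
                    seen.add(r)
                    stack.append(r)
        return frozenset(seen)

    def with_absorbing(self, state: int) -> "MultistateModelSpec":
        """Copy of the spec with ``state`` made absorbing (outgoing transitions removed)."""
        trans = tuple(t for t in self.transitions if t[0] != state)
        return MultistateModelSpec(
            n_states=self.n_states,
            transitions=trans,
            absorbing=self.absorbing | {state},
            cutpoints=self.cutpoints,
            baseline={t: self.baseline[t] for t in trans},
            design={t: self.design[t] for t in trans},
            state_names=self.state_names,
        )


@dataclass
class ParameterVector:
    """Named parameters: per-family piecewise log-baselines plus coefficients.

    ``log_baseline[family]`` is an array of length ``spec.n_pieces``
    (log intensity per year on each baseline piece); ``coefficients``
    maps coefficient name to value.  The estimation scale is fully
    unconstrained: baselines enter through their logarithm and
    coefficients linearly, which is also the scale on which fitted
    models report estimates and standard errors.
    """

    log_baseline: dict[str, np.ndarray]
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.log_baseline = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in self.log_baseline.items()}
        self.coefficients = {k: float(v) for k, v in self.coefficients.items()}
        for k, v in self.log_baseline.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite log baseline for family {k!r}")
        if any(not np.isfinite(v) for v in self.coefficients.values()):
            raise ValueError("non-finite coefficient")

    def validate_for(self, spec: MultistateModelSpec) -> None:
        for fam in spec.baseline_families:
            if fam not in self.log_baseline:
                raise ValueError(f"missing baseline family {fam!r}")
            if len(self.log_baseline[fam]) != spec.n_pieces:
                raise ValueError(
                    f"family {fam!r} has {len(self.log_baseline[fam])} pieces, spec needs {spec.n_pieces}"
                )
        for name in spec.coefficient_names:
            if name not in self.coefficients:
                raise ValueError(f"missing coefficient {name!r}")

    def to_array(self, spec: MultistateModelSpec) -> np.ndarray:
        self.validate_for(spec)
        parts = [np.asarray(self.log_baseline[fam], dtype=float) for fam in spec.baseline_families]
        parts.append(np.array([self.coefficients[c] for c in spec.coefficient_names]))
        return np.concatenate(parts) if parts else np.empty(0)

    @classmethod
    def from_array(cls, spec: MultistateModelSpec, x: Sequence[float]) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        nb = len(spec.baseline_families) * spec.n_pieces
        if x.size != nb + len(spec.coefficient_names):
            raise ValueError("parameter array length mismatch")
        lb = {
            fam: x[i * spec.n_pieces:(i + 1) * spec.n_pieces].copy()
            for i, fam in enumerate(spec.baseline_families)
        }
        coefs = dict(zip(spec.coefficient_names, x[nb:]))
        return cls(log_baseline=lb, coefficients=coefs)


def piece_index(cutpoints: Sequence[float], t: float) -> int:
    """Index of the baseline piece containing ``t``.

    Pieces are the half-open intervals [0,c_1), [c_1,c_2), ..., [c_m,inf):
    a time exactly at a cut-point belongs to the *later* piece.
    """
    return int(np.searchsorted(np.asarray(cutpoints, dtype=float), t, side="right"))


def _linear_predictor(terms: Iterable[Term], coefs: Mapping[str, float], cov: Mapping[str, float]) -> float:
    lp = 0.0
    for term in terms:
        x = term.scale
        if term.covariate is not None:
            try:
                v = cov[term.covariate]
            except KeyError:
                raise CovariateError(term.covariate) from None
            if not np.isfinite(v):
                raise ValueError(f"non-finite covariate {term.covariate!r}")
            x *= v
        lp += coefs[term.coef] * x
    return lp


def build_generator(
    spec: MultistateModelSpec,
    params: ParameterVector,
    cov: Mapping[str, float],
    t: float,
) -> np.ndarray:
    """Generator matrix Q(t | V): off-diagonal intensities, diagonal = -row sum."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    params.validate_for(spec)
    j = piece_index(spec.cutpoints, t)
    q = np.zeros((spec.n_states, spec.n_states))
    for (k, r) in spec.transitions:
        lp = _linear_predictor(spec.design[(k, r)], params.coefficients, cov)
        q[k, r] = np.exp(params.log_baseline[spec.baseline[(k, r)]][j] + lp)
    q[np.diag_indices_from(q)] = -q.sum(axis=1)
    return q


def _interval_pieces(cutpoints: Sequence[float], t0: float, t1: float) -> list[tuple[int, float]]:
    """Split [t0, t1] at interior cut-points -> [(piece index, duration), ...] in time order."""
    if t1 < t0:
        raise ValueError(f"need t0 <= t1, got {t0} > {t1}")
    edges = [t0] + [c for c in cutpoints if t0 < c < t1] + [t1]
    return [
        (piece_index(cutpoints, a), b - a)
        for a, b in zip(edges, edges[1:])
        if b > a
    ]


def transition_probability(
    spec: MultistateModelSpec,
    params: ParameterVector,
    cov: Mapping[str, float],
    t0: float,
    t1: float,
) -> np.ndarray:
    """P(Z(t1)=r | Z(t0)=k, V) as a stochastic matrix.

    The interval is split at interior baseline cut-points; within each
    piece the chain is time-homogeneous and contributes exp(Q * dt).
    """
    if t0 < 0:
        raise ValueError("t0 must be nonnegative")
    p = np.eye(spec.n_states)
    for j, dt in _interval_pieces(spec.cutpoints, t0, t1):
        # generator is constant on the piece; evaluate at the piece start
        q = build_generator(spec, params, cov, _piece_start(spec.cutpoints, j))
        p = p @ expm(q * dt)
    return p


def _piece_start(cutpoints: Sequence[float], j: int) -> float:
    return 0.0 if j == 0 else cutpoints[j - 1]


def state_entry_risk(
    spec: MultistateModelSpec,
    params: ParameterVector,
    cov: Mapping[str, float],
    start_state: int,
    target_state: int,
    horizon: float,
    t0: float = 0.0,
) -> float:
    """P(T_target <= t0 + horizon | Z(t0) = start, V).

    Computed by making the target state absorbing (so the chain cannot
    leave it once entered) and reading off the transition probability —
    i.e. the probability of having *entered* the target by the horizon,
    not of occupying it then.
    """
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    if target_state not in spec.reachable(start_state):
        raise ValueError(f"state {target_state} is not reachable from {start_state}")
    mod = spec.with_absorbing(target_state)
    p = transition_probability(mod, params, cov, t0, t0 + horizon)
    return float(p[start_state, target_state])
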