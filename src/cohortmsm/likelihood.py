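"""Panel-data likelihood for multistate models, and its maximization.

Subjects are seen only at clinic-visit (assessment) times; between
visits the path is interval-censored.  Under a Markov model whose
intensities depend on covariates held at their last-assessment values,
the observed-data likelihood factors over consecutive assessment pairs:

    log L = sum_i sum_{j=1..m_i} log P(Z_i(a_ij) | Z_i(a_{i,j-1}), V_i(a_{i,j-1}))

The first assessment of each subject is conditioned on and contributes
nothing — this is the prospective likelihood under delayed entry (the
subject's entry time is simply their first assessment time), which is
valid when enrolment is conditionally independent of the process and the
state at entry, together with covariates, is a sufficient history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from ._expm import expm_batch
from .model import (
    MultistateModelSpec,
    ParameterVector,
    _interval_pieces,
    piece_index,
)

__all__ = [
    "PanelDataset",
    "PanelLikelihood",
    "FitResult",
    "panel_log_likelihood",
    "fit_panel_mle",
    "relative_risk_table",
    "wald_rr",
]

_RESERVED = ("subject_id", "time", "state")


def _expm_shared_generator(q: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """exp(q * dt) for one generator and many durations, by uniformization.

    With uniformization rate ``c = max |diagonal|`` the matrix
    ``M = I + Q/c`` is elementwise nonnegative and
    exp(Q t) = sum_n Poisson(n; c t) M^n, so every computed probability
    is nonnegative by construction.  Falls back to scaling-and-squaring
    when c*dt is large (only reached at extreme parameter values).
    """
    from scipy.special import gammaln

    k = q.shape[0]
    c = float(-q.diagonal().min())
    x = c * dts
    if c <= 0:
        return np.broadcast_to(np.eye(k), (len(dts), k, k)).copy()
    xmax = float(x.max())
    if xmax > 30.0:
        return expm_batch(q * dts[:, None, None])
    # Poisson tail beyond x + 8*sqrt(x) + 16 is < 1e-12 for x <= 30
    n_terms = int(np.ceil(xmax + 8.0 * np.sqrt(xmax) + 16.0))
    m = np.eye(k) + q / c
    mpow = np.empty((n_terms + 1, k, k))
    mpow[0] = np.eye(k)
    for n in range(1, n_terms + 1):
        mpow[n] = mpow[n - 1] @ m
    ns = np.arange(n_terms + 1)
    safe_x = np.where(x > 0, x, 1.0)
    logw = -x[:, None] + ns * np.log(safe_x)[:, None] - gammaln(ns + 1.0)
    w = np.exp(logw)
    w[x == 0] = 0.0
    w[x == 0, 0] = 1.0
    return np.einsum("mn,nij->mij", w, mpow)


@dataclass
class PanelDataset:
    """Long-format panel observations: one row per subject-assessment.

    ``frame`` has columns ``subject_id``, ``time`` (years), ``state``
    (integer code) and one column per covariate; rows are sorted by
    subject and time at construction.  A subject's first row is their
    study-entry assessment (delayed entry is the generic case: the entry
    time is just the first assessment time).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _RESERVED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"panel frame missing columns {missing}")
        df = self.frame.sort_values(["subject_id", "time"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["subject_id", "time"]).any():
            dup = df[df.duplicated(["subject_id", "time"])]["subject_id"].iloc[0]
            raise ValueError(f"duplicate assessment time for subject {dup!r}")
        if len(df) and not np.isfinite(df["time"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite assessment time")
        self.frame = df

    @property
    def covariate_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c not in _RESERVED)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def validate_for(self, spec: MultistateModelSpec) -> None:
        df = self.frame
        states = df["state"].to_numpy()
        if len(df) == 0:
            return
        if states.min() < 0 or states.max() >= spec.n_states:
            bad = int(states[(states < 0) | (states >= spec.n_states)][0])
            raise ValueError(f"state code {bad} outside the model state space")
        for name in spec.covariate_names:
            if name not in df.columns:
                raise ValueError(f"covariate {name!r} required by the model is absent from the panel")
        sid = df["subject_id"].to_numpy()
        same = sid[1:] == sid[:-1]
        if np.any(same & ~(df["time"].to_numpy()[1:] > df["time"].to_numpy()[:-1])):
            i = int(np.nonzero(same & ~(df["time"].to_numpy()[1:] > df["time"].to_numpy()[:-1]))[0][0])
            raise ValueError(f"non-increasing assessment times for subject {sid[i]!r}")
        absorbing = np.isin(states, list(spec.absorbing))
        first = ~np.concatenate([[False], same])
        if np.any(first & absorbing):
            s = sid[first & absorbing][0]
            raise ValueError(f"subject {s!r} begins in an absorbing state")
        if np.any(same & absorbing[:-1]):
            s = sid[:-1][same & absorbing[:-1]][0]
            raise ValueError(f"subject {s!r} has assessments after entering an absorbing state")

    def concat(self, other: "PanelDataset") -> "PanelDataset":
        return PanelDataset(pd.concat([self.frame, other.frame], ignore_index=True))


class PanelLikelihood:
    """Vectorized evaluator of the panel log-likelihood for one spec+dataset.

    Precomputes, once, the interval structure (consecutive assessment
    pairs, their baseline-piece segmentation, per-interval covariates and
    per-transition design rows); each evaluation then builds all segment
    generators in a batch, exponentiates them with batched
    scaling-and-squaring, chains segments within intervals, and sums the
    log transition probabilities.
    """

    def __init__(
        self,
        spec: MultistateModelSpec,
        data: PanelDataset,
        exact_death_states: Sequence[int] = (),
    ):
        data.validate_for(spec)
        self.spec = spec
        self.data = data
        self.exact_death_states = frozenset(int(s) for s in exact_death_states)
        for s in self.exact_death_states:
            if s not in spec.absorbing:
                raise ValueError(f"exactly observed state {s} must be absorbing")

        df = data.frame
        sid = df["subject_id"].to_numpy()
        t = df["time"].to_numpy(dtype=float)
        z = df["state"].to_numpy(dtype=int)
        same = np.concatenate([[False], sid[1:] == sid[:-1]])
        left = np.nonzero(same)[0] - 1
        right = np.nonzero(same)[0]
        self.k = z[left]
        self.r = z[right]
        self.t0 = t[left]
        self.t1 = t[right]
        self.subject = sid[right]
        n_int = len(left)
        self.n_intervals = n_int

        cov_cols = list(spec.covariate_names)
        xcov = df.iloc[left][cov_cols].to_numpy(dtype=float) if cov_cols else np.zeros((n_int, 0))
        if xcov.size and not np.isfinite(xcov).all():
            raise ValueError("non-finite covariate value at an interval's left assessment")

        # infeasible observed moves (target unreachable from source) give a
        # structurally zero probability for every parameter value
        reach = {k: spec.reachable(k) for k in set(self.k)}
        self.infeasible = np.array([r not in reach[k] for k, r in zip(self.k, self.r)])

        # segment decomposition
        seg_interval, seg_piece, seg_dur, seg_pos = [], [], [], []
        for i in range(n_int):
            for p, (j, d) in enumerate(_interval_pieces(spec.cutpoints, self.t0[i], self.t1[i])):
                seg_interval.append(i)
                seg_piece.append(j)
                seg_dur.append(d)
                seg_pos.append(p)
        self.seg_interval = np.asarray(seg_interval, dtype=int)
        self.seg_piece = np.asarray(seg_piece, dtype=int)
        self.seg_dur = np.asarray(seg_dur, dtype=float)
        self.seg_pos = np.asarray(seg_pos, dtype=int)
        self.max_pos = int(self.seg_pos.max()) if n_int else -1

        # design: per transition, (n_intervals, n_coef) matrix of regressors
        self.coef_names = spec.coefficient_names
        cidx = {c: i for i, c in enumerate(self.coef_names)}
        vidx = {v: i for i, v in enumerate(cov_cols)}
        n_coef = len(self.coef_names)
        self.trans = list(spec.transitions)
        fam_index = {f: i for i, f in enumerate(spec.baseline_families)}
        self.fam_of_trans = np.array([fam_index[spec.baseline[tr]] for tr in self.trans])
        design = np.zeros((len(self.trans), n_int, n_coef))
        for ti, tr in enumerate(self.trans):
            for term in spec.design[tr]:
                col = np.full(n_int, term.scale)
                if term.covariate is not None:
                    col = col * xcov[:, vidx[term.covariate]]
                design[ti, :, cidx[term.coef]] += col
        self.design = design
        self.n_baseline = len(spec.baseline_families) * spec.n_pieces
        self.n_params = self.n_baseline + n_coef

        # for exactly observed absorbing entries: piece of the right endpoint
        self.exact = (
            np.isin(self.r, list(self.exact_death_states))
            if self.exact_death_states
            else np.zeros(n_int, dtype=bool)
        )
        self.right_piece = np.array([piece_index(spec.cutpoints, x) for x in self.t1], dtype=int)

        # Segments sharing (baseline piece, covariate row) share a generator;
        # with categorical covariates there are few distinct generators and
        # exp(Q*dt) over the many dt values is cheaper via uniformization.
        key = np.column_stack([self.seg_piece.astype(float), xcov[self.seg_interval]])
        if len(key):
            _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
            # the per-group python loop only pays off when there are few
            # distinct generators (categorical covariates, few pieces)
            if len(first) <= min(64, max(1, len(key) // 8)):
                self.seg_groups = [np.nonzero(inverse == g)[0] for g in range(len(first))]
            else:
                self.seg_groups = None
        else:
            self.seg_groups = None

    # -- evaluation ----------------------------------------------------

    def _rates(self, x: np.ndarray, seg: bool = True) -> np.ndarray:
        """Per-segment (or per right endpoint) rate of each transition."""
        spec = self.spec
        lb = x[: self.n_baseline].reshape(len(spec.baseline_families), spec.n_pieces)
        coefs = x[self.n_baseline:]
        lin = np.einsum("tnc,c->nt", self.design, coefs) if coefs.size else np.zeros((self.n_intervals, len(self.trans)))
        piece = self.seg_piece if seg else self.right_piece
        interval = self.seg_interval if seg else np.arange(self.n_intervals)
        # clip keeps exploratory optimizer steps finite; rates beyond
        # e^30 per year are far outside any plausible region
        lograte = lb[self.fam_of_trans][:, piece].T + lin[interval]
        return np.exp(np.clip(lograte, -30.0, 30.0))

    def interval_probabilities(self, x: np.ndarray) -> np.ndarray:
        """P or density contribution of each observation interval."""
        kk = self.spec.n_states
        rates = self._rates(x)  # (S, T)
        q = np.zeros((len(self.seg_dur), kk, kk))
        for ti, (a, b) in enumerate(self.trans):
            q[:, a, b] = rates[:, ti]
        ii = np.arange(kk)
        q[:, ii, ii] = -q.sum(axis=2)
        if self.seg_groups is None:
            pseg = expm_batch(q * self.seg_dur[:, None, None])
        else:
            pseg = np.empty_like(q)
            for idx in self.seg_groups:
                pseg[idx] = _expm_shared_generator(q[idx[0]], self.seg_dur[idx])
        p = np.empty((self.n_intervals, kk, kk))
        m0 = self.seg_pos == 0
        p[self.seg_interval[m0]] = pseg[m0]
        for pos in range(1, self.max_pos + 1):
            m = self.seg_pos == pos
            idx = self.seg_interval[m]
            p[idx] = p[idx] @ pseg[m]
        probs = p[np.arange(self.n_intervals), self.k, self.r]
        if self.exact.any():
            # density of an exactly observed entry to an absorbing state:
            # sum_s P(t0,t1)[k,s] * q_{s->r}(t1) over transient s
            rates_end = self._rates(x, seg=False)
            idx = np.nonzero(self.exact)[0]
            for i in idx:
                dens = 0.0
                for ti, (a, b) in enumerate(self.trans):
                    if b == self.r[i]:
                        dens += p[i, self.k[i], a] * rates_end[i, ti]
                probs[i] = dens
        return probs

    def loglik(self, x: np.ndarray) -> float:
        if self.n_intervals == 0:
            return 0.0
        if self.infeasible.any():
            # structurally zero regardless of parameters: disallowed path
            self._warn_zero(np.nonzero(self.infeasible)[0])
            return -np.inf
        probs = self.interval_probabilities(np.asarray(x, dtype=float))
        if np.any(probs <= 0):
            # numerical underflow at extreme parameter values; no diagnostic,
            # the optimizer simply backs away from the region
            return -np.inf
        return float(np.log(probs).sum())

    def _warn_zero(self, idx: np.ndarray) -> None:
        msgs = [
            f"subject {self.subject[i]}, interval ({self.t0[i]:g}, {self.t1[i]:g}], "
            f"observed {self.k[i]}->{self.r[i]}"
            for i in idx[:5]
        ]
        warnings.warn(
            "zero-probability observed transition(s): " + "; ".join(msgs)
            + ("" if len(idx) <= 5 else f" (+{len(idx) - 5} more)"),
            stacklevel=3,
        )

    def crude_initial(self) -> np.ndarray:
        """Occurrence/exposure starting values: per-family log crude rates, zero coefficients."""
        spec = self.spec
        x = np.zeros(self.n_params)
        fam_events = np.zeros(len(spec.baseline_families))
        fam_exposure = np.zeros(len(spec.baseline_families))
        dt = self.t1 - self.t0
        for ti, (a, b) in enumerate(self.trans):
            fi = self.fam_of_trans[ti]
            fam_events[fi] += np.sum((self.k == a) & (self.r == b))
            fam_exposure[fi] += dt[self.k == a].sum()
        rate = np.maximum(fam_events, 0.5) / np.maximum(fam_exposure, 1e-8)
        lb = np.repeat(np.log(rate), spec.n_pieces)
        x[: self.n_baseline] = lb
        return x


def panel_log_likelihood(
    spec: MultistateModelSpec,
    params: ParameterVector,
    data: PanelDataset,
    exact_death_states: Sequence[int] = (),
) -> float:
    """Log-likelihood of panel data under the model (see module docstring)."""
    ev = PanelLikelihood(spec, data, exact_death_states)
    return ev.loglik(params.to_array(spec))


@dataclass
class FitResult:
    """Maximum-likelihood fit of a multistate model to panel data."""

    spec: MultistateModelSpec
    params: ParameterVector
    loglik: float
    converged: bool
    n_iter: int
    message: str
    x: np.ndarray
    covariance: np.ndarray | None = None
    parameter_names: tuple[str, ...] = ()
    n_subjects: int = 0
    n_intervals: int = 0

    @property
    def se(self) -> dict[str, float]:
        names = self.parameter_names or self.spec.parameter_names()
        if self.covariance is None:
            return {n: float("nan") for n in names}
        d = np.diag(self.covariance)
        return {n: (float(np.sqrt(v)) if v >= 0 else float("nan")) for n, v in zip(names, d)}

    def estimate(self, name: str) -> float:
        names = self.parameter_names or self.spec.parameter_names()
        try:
            return float(self.x[names.index(name)])
        except ValueError:
            raise KeyError(name) from None


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def fit_panel_mle(
    spec: MultistateModelSpec,
    data: PanelDataset,
    init: ParameterVector | None = None,
    *,
    exact_death_states: Sequence[int] = (),
    compute_se: bool = True,
    gtol: float = 1e-6,
    maxiter: int = 500,
    n_starts: int = 1,
    jitter: float = 0.3,
    seed: int | None = None,
) -> FitResult:
    """Maximize the panel log-likelihood by quasi-Newton (BFGS) iteration.

    Standard errors come from the inverse of the numerically
    differentiated observed information at the optimum; when that matrix
    is not invertible (or not positive) the corresponding s.e. are
    reported as NaN rather than fabricated.  Deterministic given the
    data, starting point and options.
    """
    ev = PanelLikelihood(spec, data, exact_death_states)
    observed = {(a, b) for a, b in zip(ev.k, ev.r) if a != b}
    unobserved = [tr for tr in spec.transitions if tr not in observed]
    if unobserved and ev.n_intervals:
        warnings.warn(
            f"transitions never observed directly in the panel: {unobserved}; "
            "the corresponding intensities may be weakly identified",
            stacklevel=2,
        )

    x0 = init.to_array(spec) if init is not None else ev.crude_initial()

    def nll(x: np.ndarray) -> float:
        ll = ev.loglik(x)
        return 1e12 if not np.isfinite(ll) else -ll

    starts = [x0]
    if n_starts > 1:
        rng = np.random.default_rng(seed)
        starts += [x0 + jitter * rng.standard_normal(len(x0)) for _ in range(n_starts - 1)]

    best = None
    for s in starts:
        res = optimize.minimize(
            nll,
            s,
            method="L-BFGS-B",
            options={"ftol": 1e-11, "gtol": gtol, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    cov = None
    if compute_se:
        hess = _numeric_hessian(nll, best.x)
        try:
            cov = np.linalg.inv(hess)
            if not np.all(np.isfinite(cov)):
                cov = None
        except np.linalg.LinAlgError:
            cov = None

    return FitResult(
        spec=spec,
        params=ParameterVector.from_array(spec, best.x),
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_iter=int(best.nit),
        message=str(best.message),
        x=best.x.copy(),
        covariance=cov,
        parameter_names=spec.parameter_names(),
        n_subjects=data.n_subjects,
        n_intervals=ev.n_intervals,
    )


def wald_rr(est: float, se: float, z: float = 1.96) -> tuple[float, float, float]:
    """Relative risk exp(est) with Wald 95% limits exp(est -/+ z*se)."""
    return float(np.exp(est)), float(np.exp(est - z * se)), float(np.exp(est + z * se))


def relative_risk_table(
    fit: FitResult,
    coefficients: Sequence[str] | None = None,
    combinations: Mapping[str, Mapping[str, float]] | None = None,
    z: float = 1.96,
) -> pd.DataFrame:
    """Exponentiated coefficients with 95% Wald intervals, Table-style.

    ``combinations`` maps a row label to weights ``{coef: c}`` for a
    linear combination c'beta; its CI uses c' Cov c and is NaN when the
    covariance is unavailable.
    """
    names = list(fit.parameter_names or fit.spec.parameter_names())
    wanted = list(coefficients) if coefficients is not None else list(fit.spec.coefficient_names)
    se = fit.se
    rows = []
    for name in wanted:
        if name not in names:
            raise KeyError(f"unknown coefficient {name!r}")
        est = fit.estimate(name)
        s = se[name]
        rr, lo, hi = wald_rr(est, s, z) if np.isfinite(s) else (np.exp(est), np.nan, np.nan)
        rows.append({"name": name, "est": est, "se": s, "rr": rr, "lo": lo, "hi": hi})
    for label, weights in (combinations or {}).items():
        idx = []
        c = np.zeros(len(names))
        for coef, w in weights.items():
            if coef not in names:
                raise KeyError(f"unknown coefficient {coef!r}")
            c[names.index(coef)] = w
            idx.append(coef)
        est = float(c @ fit.x)
        if fit.covariance is not None:
            s = float(np.sqrt(max(c @ fit.covariance @ c, 0.0)))
            rr, lo, hi = wald_rr(est, s, z)
        else:
            s, rr, lo, hi = np.nan, float(np.exp(est)), np.nan, np.nan
        rows.append({"name": label, "est": est, "se": s, "rr": rr, "lo": lo, "hi": hi})
    return pd.DataFrame(rows).set_index("name")
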