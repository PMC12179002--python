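"""Named joint-process model builders and registry enrolment models.

Three model families recur in cohort studies of psoriatic disease:

* a two-state onset model (psoriasis -> psoriatic arthritis) with fixed
  covariates — optionally extended with a death state;
* an 8-state joint process for a binary inflammation marker X(t)
  (elevated ESR), biologic-treatment status B(t) and a failure endpoint
  Z(t) (arthritis mutilans), whose states are the triples (Z, X, B);
* a 6-state illness-death process crossed with cohort-enrolment status,
  used to study what self-selected (type B) recruitment does to
  estimated intensities.

Each builder returns an ordinary :class:`~cohortmsm.model.MultistateModelSpec`
with the parameter sharing wired through baseline families and shared
coefficient names, so the generic likelihood machinery applies unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import log_expit

from .likelihood import FitResult
from .model import MultistateModelSpec, Term

__all__ = [
    "FMT_STATES",
    "fmt_state_code",
    "fmt_state_decode",
    "RegistryRecord",
    "build_psa_onset_model",
    "build_fmt_model",
    "build_illness_death_enrolment_model",
    "combined_effect_rr",
    "registry_enrolment_loglik",
    "fit_registry_enrolment",
]


# ---------------------------------------------------------------------------
# 8-state (Z, X, B) coding
# ---------------------------------------------------------------------------

def fmt_state_code(z: int, x: int, b: int) -> int:
    """Code for the (failure, marker, treatment) triple: ``4*Z + 2*X + B``."""
    for v in (z, x, b):
        if v not in (0, 1):
            raise ValueError("Z, X, B must be binary")
    return 4 * z + 2 * x + b


def fmt_state_decode(code: int) -> tuple[int, int, int]:
    """Inverse of :func:`fmt_state_code`: code -> (Z, X, B)."""
    if not 0 <= code <= 7:
        raise ValueError("state code must be in 0..7")
    return (code >> 2) & 1, (code >> 1) & 1, code & 1


FMT_STATES: tuple[str, ...] = tuple(
    "Z{}X{}B{}".format(*fmt_state_decode(c)) for c in range(8)
)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_psa_onset_model(
    covariate_names: Sequence[str] = ("V1", "V2", "V3"),
    include_death: bool = False,
) -> MultistateModelSpec:
    """Two-state onset model: psoriasis (0) -> psoriatic arthritis (1).

    One baseline piece (time-homogeneous), a single transition whose
    multiplier is log-linear in the fixed covariates — by convention
    V1 = age at psoriasis onset centered at 40 (years), V2 = sex
    (1 = male), V3 = HLA-B27 (1 = positive), with coefficients theta1..
    With ``include_death`` a terminal death state (2) is added with its
    own covariate-free intensities from both living states; setting
    those to zero recovers the two-state risks exactly.
    """
    design = tuple(
        Term(coef=f"theta{i + 1}", covariate=name) for i, name in enumerate(covariate_names)
    )
    if not include_death:
        return MultistateModelSpec(
            n_states=2,
            transitions=((0, 1),),
            absorbing=frozenset({1}),
            baseline={(0, 1): "lambda12"},
            design={(0, 1): design},
            state_names=("Ps", "PsA"),
        )
    return MultistateModelSpec(
        n_states=3,
        transitions=((0, 1), (0, 2), (1, 2)),
        absorbing=frozenset({2}),
        baseline={(0, 1): "lambda12", (0, 2): "lambda13", (1, 2): "lambda23"},
        design={(0, 1): design},
        state_names=("Ps", "PsA", "Dead"),
    )


def build_fmt_model(
    cutpoints: Sequence[float] = (5.0, 10.0),
    covariate_names: Sequence[str] = ("V1", "V2", "V3"),
) -> MultistateModelSpec:
    """8-state joint failure/marker/treatment model over (Z, X, B) triples.

    Time is measured from the start of the calendar observation window;
    the piecewise-constant baselines (default cut-points at 5 and 10
    years) absorb secular trends such as growing biologics availability.

    Allowed transitions (failure states are absorbing — the endpoint
    terminates the analysis):

    * marker flips ``(0,x,b) -> (0,1-x,b)``: intensity
      ``lx_k0(t) * exp(B eta_k1 + V' eta_k2)`` with k = 1 for the 0->1
      flip and k = 0 for 1->0; the four transitions per direction share
      one baseline family and one coefficient set, with the treatment
      indicator read off the source state;
    * treatment initiation ``(0,x,0) -> (0,x,1)``:
      ``lb0(t) * exp(X phi1 + V' phi2)``, treatment never stops;
    * failure ``(0,x,b) -> (1,x,b)``:
      ``lz0(t) * exp(X beta1 + B beta2 + X*B beta3 + V' beta4)``.

    The covariate coefficient vector on the failure intensity is named
    beta4 (beta1..beta3 are the marker, treatment and interaction
    effects).
    """
    cov = tuple(covariate_names)

    def vterms(prefix: str) -> tuple[Term, ...]:
        return tuple(Term(coef=f"{prefix}_{c}", covariate=c) for c in cov)

    transitions: dict[tuple[int, int], tuple[str, tuple[Term, ...]]] = {}
    for x in (0, 1):
        for b in (0, 1):
            src = fmt_state_code(0, x, b)
            # marker flip
            dst = fmt_state_code(0, 1 - x, b)
            k = 1 - x  # k=1 names the 0->1 flip, k=0 the 1->0 flip
            terms = (Term(coef=f"eta{k}1", scale=float(b)),) if b else ()
            transitions[(src, dst)] = (f"x{'01' if k else '10'}", terms + vterms(f"eta{k}2"))
            # failure
            dst = fmt_state_code(1, x, b)
            terms = ()
            if x:
                terms += (Term(coef="beta1", scale=1.0),)
            if b:
                terms += (Term(coef="beta2", scale=1.0),)
            if x and b:
                terms += (Term(coef="beta3", scale=1.0),)
            transitions[(src, dst)] = ("z01", terms + vterms("beta4"))
            # treatment initiation
            if b == 0:
                dst = fmt_state_code(0, x, 1)
                terms = (Term(coef="phi1", scale=1.0),) if x else ()
                transitions[(src, dst)] = ("b01", terms + vterms("phi2"))

    return MultistateModelSpec(
        n_states=8,
        transitions=tuple(transitions),
        absorbing=frozenset({fmt_state_code(1, x, b) for x in (0, 1) for b in (0, 1)}),
        cutpoints=tuple(cutpoints),
        baseline={tr: fam for tr, (fam, _) in transitions.items()},
        design={tr: terms for tr, (_, terms) in transitions.items()},
        state_names=FMT_STATES,
    )


def build_illness_death_enrolment_model(pre_post_shared: bool = True) -> MultistateModelSpec:
    """Illness-death process crossed with cohort-enrolment status.

    States 0, 1, 2 are healthy/ill/dead *outside* the cohort; 3, 4, 5
    are the same disease states after enrolment.  Disease intensities
    carry a pre-enrolment ring (families ``lam01_pre`` etc.) and a
    post-enrolment version (``lam01`` etc.); enrolment occurs from the
    living unenrolled states with intensities ``rho0`` (healthy) and
    ``rho1`` (ill).  Enrolment status never reverses, so it is a
    non-decreasing indicator along every allowed path.

    With ``pre_post_shared`` the pre- and post-enrolment disease
    families are tied (identical names), which is exactly the
    conditional-independence condition under which cohort-based
    estimates generalize to the population.
    """
    suffix = "" if pre_post_shared else "_pre"
    baseline = {
        (0, 1): "lam01" + suffix,
        (0, 2): "lam02" + suffix,
        (1, 2): "lam12" + suffix,
        (0, 3): "rho0",
        (1, 4): "rho1",
        (3, 4): "lam01",
        (3, 5): "lam02",
        (4, 5): "lam12",
    }
    return MultistateModelSpec(
        n_states=6,
        transitions=tuple(baseline),
        absorbing=frozenset({2, 5}),
        baseline=baseline,
        state_names=("healthy*", "ill*", "dead*", "healthy", "ill", "dead"),
    )


# ---------------------------------------------------------------------------
# Derived effects
# ---------------------------------------------------------------------------

def combined_effect_rr(fit: FitResult | Mapping[str, float], coefficient_names: Iterable[str]) -> float:
    """Relative risk of a combination of effects: exp(sum of the named estimates).

    Used e.g. for the effect of biologic treatment in the presence of an
    elevated marker, where the treatment main effect and the
    marker-treatment interaction add on the log scale.  Accepts a fitted
    model or a plain name->estimate mapping (printed estimates).
    """
    total = 0.0
    for name in coefficient_names:
        if isinstance(fit, Mapping):
            if name not in fit:
                raise KeyError(f"unknown coefficient {name!r}")
            total += float(fit[name])
        else:
            total += fit.estimate(name)
    return float(np.exp(total))


# ---------------------------------------------------------------------------
# Registry enrolment (two-phase selection) models
# ---------------------------------------------------------------------------

@dataclass
class RegistryRecord:
    """One phase-1 (registry) member's enrolment outcome.

    ``delta`` indicates enrolment in the cohort by the evaluation time
    ``time`` (the entry time for enrollees, the end of recruitment for
    the rest); ``covariates`` is the registry information available at
    that time, on which selection may depend.
    """

    id: object
    delta: int
    time: float
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta not in (0, 1):
            raise ValueError("delta must be 0 or 1")
        if self.time < 0:
            raise ValueError("evaluation time must be nonnegative")


def _linear_predictors(records: Sequence[RegistryRecord], coefficients: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(records))
    for j, rec in enumerate(records):
        v = coefficients.get("intercept", 0.0)
        for name, coef in coefficients.items():
            if name == "intercept":
                continue
            if name not in rec.covariates:
                raise KeyError(f"record {rec.id!r} lacks covariate {name!r}")
            v += coef * rec.covariates[name]
        lp[j] = v
    return lp


def registry_enrolment_loglik(
    records: Sequence[RegistryRecord],
    coefficients: Mapping[str, float],
) -> float:
    """Product-binomial log-likelihood of registry enrolment indicators.

    Each registry member contributes ``delta*log(pi) + (1-delta)*log(1-pi)``
    with ``pi = expit(intercept + coef' covariates)``; the logistic form
    for the selection probability is this package's modelling choice.
    """
    if not records:
        return 0.0
    lp = _linear_predictors(records, coefficients)
    delta = np.array([r.delta for r in records], dtype=float)
    ll = delta * log_expit(lp) + (1.0 - delta) * log_expit(-lp)
    if not np.all(np.isfinite(ll)):
        i = int(np.nonzero(~np.isfinite(ll))[0][0])
        warnings.warn(
            f"degenerate selection probability contradicts the outcome for record "
            f"{records[i].id!r} (delta={records[i].delta})",
            stacklevel=2,
        )
        return -np.inf
    return float(ll.sum())


def fit_registry_enrolment(
    records: Sequence[RegistryRecord],
    covariate_names: Sequence[str],
    init: Mapping[str, float] | None = None,
) -> dict:
    """Maximize the registry enrolment likelihood over logistic coefficients.

    Returns estimates, standard errors (inverse observed information)
    and the maximized log-likelihood.
    """
    from scipy import optimize

    names = ["intercept", *covariate_names]
    x0 = np.array([(init or {}).get(n, 0.0) for n in names])

    def nll(x: np.ndarray) -> float:
        ll = registry_enrolment_loglik(records, dict(zip(names, x)))
        return 1e12 if not np.isfinite(ll) else -ll

    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-8})
    # observed information of the logistic model in closed form
    lp = _linear_predictors(records, dict(zip(names, res.x)))
    p = 1.0 / (1.0 + np.exp(-lp))
    xmat = np.column_stack(
        [np.ones(len(records))]
        + [np.array([r.covariates[n] for r in records]) for n in covariate_names]
    )
    info = (xmat * (p * (1 - p))[:, None]).T @ xmat
    try:
        cov = np.linalg.inv(info)
        se = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    except np.linalg.LinAlgError:
        cov, se = None, {n: float("nan") for n in names}
    return {
        "estimates": dict(zip(names, res.x)),
        "se": se,
        "covariance": cov,
        "loglik": -float(res.fun),
        "converged": bool(res.success),
    }
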