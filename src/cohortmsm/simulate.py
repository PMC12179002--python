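"""Synthetic-cohort engine: trajectories, visit processes, enrolment.

Generates fully observed continuous-time paths of a multistate model,
overlays an independent clinic-visit (assessment) process, applies a
type A (externally timed) or type B (self-selected, intensity-driven)
enrolment mechanism with an end-of-recruitment window, and emits the
panel data an analyst would actually see — the state and last-known
covariates at each visit from study entry onward.  The full paths,
entry times and a registry table (enrolment indicator for *every*
population member) are retained so that selection effects can be
measured against the simulation truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .joint import build_fmt_model, build_illness_death_enrolment_model, build_psa_onset_model, fmt_state_code
from .likelihood import PanelDataset
from .model import MultistateModelSpec, ParameterVector, build_generator, piece_index

__all__ = [
    "Trajectory",
    "VisitSpec",
    "EnrolmentSpec",
    "CohortSimConfig",
    "CohortSample",
    "simulate_trajectory",
    "simulate_visits",
    "simulate_cohort",
    "make_scenario",
    "SCENARIO_NAMES",
]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A fully observed path: initial state and (time, from, to) events."""

    initial_state: int
    events: tuple[tuple[float, int, int], ...]
    t_end: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        state, t = self.initial_state, self.t_start
        for time, src, dst in self.events:
            if time <= t or src != state:
                raise ValueError("events must chain with strictly increasing times")
            state, t = dst, time
        if self.events and self.events[-1][0] > self.t_end:
            raise ValueError("event after administrative end time")

    def state_at(self, t: float) -> int:
        """State occupied at time t (paths are right-continuous)."""
        state = self.initial_state
        for time, _, dst in self.events:
            if time <= t:
                state = dst
            else:
                break
        return state

    def first_entry_time(self, states: int | Sequence[int]) -> float | None:
        """First time any of ``states`` is entered (None if never; entry at
        the start counts as time ``t_start``)."""
        targets = {states} if isinstance(states, int) else set(states)
        if self.initial_state in targets:
            return self.t_start
        for time, _, dst in self.events:
            if dst in targets:
                return time
        return None

    def transition_count(self, k: int, r: int, t: float | None = None) -> int:
        """Number of k->r transitions up to time t (all, if t is None)."""
        end = self.t_end if t is None else t
        return sum(1 for time, src, dst in self.events if src == k and dst == r and time <= end)


RateModifier = Callable[[float, int, tuple[int, int]], float]


def simulate_trajectory(
    spec: MultistateModelSpec,
    params: ParameterVector,
    cov: Mapping[str, float],
    t_max: float,
    rng: np.random.Generator,
    initial_state: int = 0,
    t_start: float = 0.0,
    rate_modifier: RateModifier | None = None,
    modifier_bound: RateModifier | None = None,
) -> Trajectory:
    """Simulate one path by competing exponentials within baseline pieces.

    Within a piece the chain is time-homogeneous: a candidate sojourn is
    drawn from the total exit rate; if it would cross the next cut-point
    the clock advances to the cut-point and the draw is repeated (valid
    by memorylessness), otherwise the destination is chosen with
    probability proportional to the rates.

    ``rate_modifier(t, state, (k, r))`` optionally scales individual
    intensities by a time-varying factor (used for duration-dependent
    enrolment); it is handled by thinning, with ``modifier_bound`` giving
    an upper bound for the factor over the remainder of the current
    piece (defaults to the factor's current value, valid when it is
    non-increasing in t).
    """
    if t_max < t_start:
        raise ValueError("t_max must be >= t_start")
    params.validate_for(spec)
    state = initial_state
    t = t_start
    events: list[tuple[float, int, int]] = []
    out: dict[int, list[tuple[int, int]]] = {}
    for tr in spec.transitions:
        out.setdefault(tr[0], []).append(tr)

    while state not in spec.absorbing and t < t_max:
        trans = out.get(state, [])
        if not trans:
            break
        j = piece_index(spec.cutpoints, t)
        next_cut = spec.cutpoints[j] if j < len(spec.cutpoints) else math.inf
        segment_end = min(next_cut, t_max)
        q = build_generator(spec, params, cov, t)
        base_rates = np.array([q[tr] for tr in trans])
        if rate_modifier is None:
            rates = base_rates
            bound = rates
        else:
            bound_fn = modifier_bound or rate_modifier
            bound = base_rates * np.array([bound_fn(t, state, tr) for tr in trans])
        total_bound = float(bound.sum())
        if total_bound <= 0:
            t = segment_end
            continue
        w = rng.exponential(1.0 / total_bound)
        if t + w >= segment_end:
            t = segment_end
            continue
        t = t + w
        if rate_modifier is not None:
            rates = base_rates * np.array([rate_modifier(t, state, tr) for tr in trans])
            if rng.uniform() * total_bound > rates.sum():
                continue  # thinned-out candidate
        dest = trans[rng.choice(len(trans), p=rates / rates.sum())]
        events.append((t, state, dest[1]))
        state = dest[1]

    return Trajectory(initial_state=initial_state, events=tuple(events), t_end=t_max, t_start=t_start)


# ---------------------------------------------------------------------------
# Visit process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisitSpec:
    """Renewal visit process: the first assessment is at study entry and
    subsequent gaps are i.i.d. from ``gap_dist`` (independent of the
    disease path by construction).

    Supported distributions: ``fixed`` (params: gap), ``exponential``
    (params: mean), ``gamma`` (params: shape, mean).
    """

    gap_dist: str = "exponential"
    gap_params: Mapping[str, float] = field(default_factory=lambda: {"mean": 0.8})

    def __post_init__(self) -> None:
        if self.gap_dist not in ("fixed", "exponential", "gamma"):
            raise ValueError(f"unknown gap distribution {self.gap_dist!r}")
        if any(v <= 0 for v in self.gap_params.values()):
            raise ValueError("visit gap parameters must be positive")

    def draw_gap(self, rng: np.random.Generator) -> float:
        p = self.gap_params
        if self.gap_dist == "fixed":
            return float(p["gap"])
        if self.gap_dist == "exponential":
            return float(rng.exponential(p["mean"]))
        shape = p["shape"]
        return float(rng.gamma(shape, p["mean"] / shape))


def simulate_visits(
    visit_spec: VisitSpec,
    entry_time: float,
    end_time: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assessment times on [entry, end]: entry itself, then renewal gaps,
    truncated at the end of follow-up."""
    if end_time < entry_time:
        raise ValueError("end_time must be >= entry_time")
    times = [entry_time]
    t = entry_time
    while True:
        t = t + visit_spec.draw_gap(rng)
        if t > end_time + 1e-12:
            break
        times.append(t)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrolmentSpec:
    """How population members become study subjects.

    ``type A``: enrolment at an externally set time (random sampling of
    the population at ``entry_time``); everyone alive then enrols.

    ``type B``: enrolment is a transition of the joint process itself
    (the model spec contains enrolment intensities); ``enrolled_states``
    are the joint states that count as "in the cohort", ``window`` is the
    end of recruitment L-dagger (enrolment intensities switch off after
    it), and ``duration_coef`` optionally scales the from-illness
    enrolment intensity by exp(duration_coef * time-since-illness).
    """

    kind: str = "A"
    entry_time: float = 0.0
    enrolled_states: tuple[int, ...] = ()
    window: float = math.inf
    duration_coef: float = 0.0
    illness_state: int | None = None  # unenrolled illness state, for duration_coef
    illness_enrol_transition: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("A", "B"):
            raise ValueError("enrolment kind must be 'A' or 'B'")
        if self.kind == "B" and not self.enrolled_states:
            raise ValueError("type B enrolment needs enrolled_states")


@dataclass(frozen=True)
class CohortSimConfig:
    """Everything needed to simulate one cohort, reproducibly.

    ``covariates`` maps name -> (dist, params) with dists ``normal``
    (mean, sd), ``bernoulli`` (p) and ``constant`` (value);
    ``covariate_groups`` lists mutually exclusive indicator blocks as
    (names, probabilities) with the remainder meaning "neither".
    ``observed_state_map`` translates simulated (joint) states to the
    analysis coding used in the emitted panel.  The seed is mandatory:
    per-subject substreams are derived from it, so enlarging the
    population does not reshuffle existing subjects.
    """

    name: str
    n: int
    spec: MultistateModelSpec
    true_params: ParameterVector
    seed: int
    covariates: Mapping[str, tuple[str, Mapping[str, float]]] = field(default_factory=dict)
    covariate_groups: tuple[tuple[tuple[str, ...], tuple[float, ...]], ...] = ()
    visit: VisitSpec = VisitSpec()
    enrolment: EnrolmentSpec = EnrolmentSpec()
    censor_time: float = 20.0
    initial_state_dist: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    observed_state_map: Mapping[int, int] | None = None
    analysis_spec: MultistateModelSpec | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population size must be positive")
        if self.censor_time <= 0:
            raise ValueError("censoring time must be positive")
        if not math.isclose(sum(self.initial_state_dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("initial state distribution must sum to 1")


@dataclass
class CohortSample:
    """One simulated cohort: the observable panel plus the full truth."""

    config: CohortSimConfig
    panel: PanelDataset
    registry: pd.DataFrame
    trajectories: list[Trajectory]
    covariate_frame: pd.DataFrame
    entry_times: np.ndarray
    enrolled: np.ndarray


def _draw_covariates(config: CohortSimConfig, rng: np.random.Generator) -> dict[str, float]:
    cov: dict[str, float] = {}
    for name, (dist, p) in config.covariates.items():
        if dist == "normal":
            cov[name] = float(rng.normal(p["mean"], p["sd"]))
        elif dist == "bernoulli":
            cov[name] = float(rng.uniform() < p["p"])
        elif dist == "constant":
            cov[name] = float(p["value"])
        else:
            raise ValueError(f"unknown covariate distribution {dist!r}")
    for names, probs in config.covariate_groups:
        u = rng.uniform()
        acc = 0.0
        chosen = None
        for nm, pr in zip(names, probs):
            acc += pr
            if u < acc and chosen is None:
                chosen = nm
        for nm in names:
            cov[nm] = float(nm == chosen)
    return cov


def _strip_enrolment(spec: MultistateModelSpec, enrolled_states: Sequence[int]) -> MultistateModelSpec:
    """Spec with transitions into enrolled states removed (recruitment over)."""
    keep = tuple(tr for tr in spec.transitions if tr[1] not in enrolled_states)
    return MultistateModelSpec(
        n_states=spec.n_states,
        transitions=keep,
        absorbing=spec.absorbing,
        cutpoints=spec.cutpoints,
        baseline={tr: spec.baseline[tr] for tr in keep},
        design={tr: spec.design[tr] for tr in keep},
        state_names=spec.state_names,
    )


def _simulate_member(
    config: CohortSimConfig,
    cov: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[Trajectory, float | None]:
    """Full path and enrolment time (None if never enrolled) for one member."""
    init_states = list(config.initial_state_dist)
    init_probs = np.array([config.initial_state_dist[s] for s in init_states])
    z0 = init_states[rng.choice(len(init_states), p=init_probs / init_probs.sum())]
    enr = config.enrolment

    if enr.kind == "A":
        traj = simulate_trajectory(config.spec, config.true_params, cov, config.censor_time, rng, z0)
        if traj.state_at(enr.entry_time) in config.spec.absorbing:
            return traj, None
        return traj, enr.entry_time

    modifier = None
    bound = None
    if enr.duration_coef != 0.0:
        if enr.illness_state is None or enr.illness_enrol_transition is None:
            raise ValueError("duration_coef needs illness_state and illness_enrol_transition")
        alpha = enr.duration_coef
        window_ref = min(enr.window, config.censor_time)
        # The simulation loop evaluates the modifier at the current clock time
        # of every iteration, so the first call made from the illness state
        # pins down the illness entry time t1.
        ill_entry: dict[str, float | None] = {"t1": None}

        def _track(t: float, state: int) -> None:
            if state == enr.illness_state and ill_entry["t1"] is None:
                ill_entry["t1"] = t

        def modifier(t: float, state: int, tr: tuple[int, int]) -> float:  # noqa: F811
            _track(t, state)
            if tr != enr.illness_enrol_transition or ill_entry["t1"] is None:
                return 1.0
            return math.exp(alpha * (t - ill_entry["t1"]))

        def bound(t: float, state: int, tr: tuple[int, int]) -> float:  # noqa: F811
            _track(t, state)
            if tr != enr.illness_enrol_transition or ill_entry["t1"] is None:
                return 1.0
            ref = t if alpha < 0 else window_ref
            return math.exp(alpha * (ref - ill_entry["t1"]))

    # phase 1: recruitment open until the window closes
    window_end = min(enr.window, config.censor_time)
    sub = simulate_trajectory(
        config.spec, config.true_params, cov, window_end, rng, z0,
        rate_modifier=modifier, modifier_bound=bound,
    )
    entry = sub.first_entry_time(enr.enrolled_states)
    events = list(sub.events)
    # phase 2: recruitment closed; unenrolled members can no longer enrol
    state = sub.state_at(window_end)
    if state not in config.spec.absorbing and window_end < config.censor_time:
        cont_spec = config.spec if entry is not None else _strip_enrolment(config.spec, enr.enrolled_states)
        tail = simulate_trajectory(
            cont_spec, config.true_params, cov, config.censor_time, rng, state, window_end
        )
        events.extend(tail.events)
    traj = Trajectory(z0, tuple(events), config.censor_time)
    return traj, entry


def simulate_cohort(config: CohortSimConfig) -> CohortSample:
    """Simulate the population, apply enrolment, and emit panel + registry data.

    Enrollees (entry by the recruitment deadline, alive at entry) get a
    visit schedule on [entry, censor] and contribute one panel row per
    visit with the state *at that visit only* — between-visit events are
    deliberately invisible, and follow-up rows after the first visit in
    an absorbing state are dropped.  All members, enrolled or not,
    contribute a registry record (enrolment indicator, evaluation time,
    covariates, and the disease state then).
    """
    smap = dict(config.observed_state_map or {})
    analysis_spec = config.analysis_spec or config.spec
    panel_rows: list[dict] = []
    registry_rows: list[dict] = []
    cov_rows: list[dict] = []
    trajectories: list[Trajectory] = []
    entry_times = np.full(config.n, np.nan)
    enrolled = np.zeros(config.n, dtype=bool)

    for i in range(config.n):
        rng = np.random.default_rng([config.seed, i])
        cov = _draw_covariates(config, rng)
        traj, entry = _simulate_member(config, cov, rng)
        trajectories.append(traj)
        cov_rows.append({"subject_id": i, **cov})

        if entry is not None:
            enrolled[i] = True
            entry_times[i] = entry
            visits = simulate_visits(config.visit, entry, config.censor_time, rng)
            for t in visits:
                z = traj.state_at(t)
                obs = smap.get(z, z)
                panel_rows.append({"subject_id": i, "time": float(t), "state": int(obs), **cov})
                if obs in analysis_spec.absorbing:
                    break

        eval_time = entry if entry is not None else min(config.enrolment.window, config.censor_time)
        registry_rows.append(
            {
                "id": i,
                "delta": int(entry is not None),
                "time": float(eval_time),
                "state_at_eval": int(traj.state_at(eval_time)),
                **cov,
            }
        )

    if not enrolled.any():
        raise ValueError(
            "no population member enrolled; increase the enrolment intensities, "
            "widen the recruitment window or enlarge the population"
        )

    panel = PanelDataset(pd.DataFrame(panel_rows))
    return CohortSample(
        config=config,
        panel=panel,
        registry=pd.DataFrame(registry_rows),
        trajectories=trajectories,
        covariate_frame=pd.DataFrame(cov_rows),
        entry_times=entry_times,
        enrolled=enrolled,
    )


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = ("utpc_table1", "fmt_table2", "enrolment_bias")

# Published point estimates for the two-state onset model (log baseline
# intensity per year, then coefficients for centered onset age, male sex
# and HLA-B27 positivity).
TABLE1_TRUTH = {
    "log_lambda12": -4.379,
    "theta1": -0.011,
    "theta2": 0.117,
    "theta3": -0.724,
}

# Published covariate coefficients for the 8-state joint model.  The
# piecewise baseline intensities were not published; the scenario values
# below are package choices giving realistic event counts (see docs).
TABLE2_TRUTH = {
    "eta01": 0.335, "eta02_V1": 0.686, "eta02_V2": -0.074, "eta02_V3": 0.0,
    "eta11": 0.120, "eta12_V1": 0.813, "eta12_V2": 0.157, "eta12_V3": 0.0,
    "phi1": 0.618, "phi2_V1": 0.347, "phi2_V2": 1.004, "phi2_V3": 0.0,
    "beta1": 0.554, "beta2": 1.081, "beta3": -1.657,
    "beta4_V1": 0.327, "beta4_V2": 1.334, "beta4_V3": 0.117,
}
FMT_BASELINES = {
    "z01": np.log([0.030, 0.040, 0.050]),   # failure
    "x01": np.log([0.250, 0.250, 0.250]),   # marker normal -> elevated
    "x10": np.log([0.350, 0.350, 0.350]),   # marker elevated -> normal
    "b01": np.log([0.060, 0.120, 0.150]),   # biologics initiation
}

ENROLMENT_BIAS_TRUTH = {
    "lam01_pre": 0.15, "lam02_pre": 0.03, "lam12_pre": 0.08,
    "rho0": 0.20, "rho1": 0.40,
}


def make_scenario(name: str, seed: int = 20260921, **overrides) -> CohortSimConfig:
    """Built-in study conditions, overridable field by field.

    ``utpc_table1``: two-state onset model at the published point
    estimates, registry-style covariates, follow-up from onset.

    ``fmt_table2``: 8-state joint marker/treatment/failure model at the
    published coefficients (baselines are package choices), calendar
    window with cut-points at 5 and 10 years.

    ``enrolment_bias``: illness-death process with self-selected (type B)
    enrolment; keyword ``divergence`` sets the log-ratio of the post- vs
    pre-enrolment illness intensity (0 = independent enrolment).
    """
    if name == "utpc_table1":
        spec = build_psa_onset_model()
        params = ParameterVector(
            log_baseline={"lambda12": [TABLE1_TRUTH["log_lambda12"]]},
            coefficients={k: v for k, v in TABLE1_TRUTH.items() if k.startswith("theta")},
        )
        cfg = CohortSimConfig(
            name=name,
            n=1500,
            spec=spec,
            true_params=params,
            seed=seed,
            covariates={
                "V1": ("normal", {"mean": 0.0, "sd": 13.0}),
                "V2": ("bernoulli", {"p": 0.5}),
                "V3": ("bernoulli", {"p": 0.08}),
            },
            visit=VisitSpec("exponential", {"mean": 0.8}),
            enrolment=EnrolmentSpec(kind="A", entry_time=0.0),
            censor_time=20.0,
        )
    elif name == "fmt_table2":
        spec = build_fmt_model()
        params = ParameterVector(
            log_baseline={k: v.copy() for k, v in FMT_BASELINES.items()},
            coefficients=dict(TABLE2_TRUTH),
        )
        cfg = CohortSimConfig(
            name=name,
            n=800,
            spec=spec,
            true_params=params,
            seed=seed,
            covariates={"V3": ("bernoulli", {"p": 0.5})},
            covariate_groups=((("V1", "V2"), (0.25, 0.25)),),
            visit=VisitSpec("exponential", {"mean": 0.8}),
            enrolment=EnrolmentSpec(kind="A", entry_time=0.0),
            censor_time=12.0,
            initial_state_dist={fmt_state_code(0, 0, 0): 0.7, fmt_state_code(0, 1, 0): 0.3},
        )
    elif name == "enrolment_bias":
        divergence = float(overrides.pop("divergence", 0.0))
        spec = build_illness_death_enrolment_model(pre_post_shared=False)
        tr = ENROLMENT_BIAS_TRUTH
        params = ParameterVector(
            log_baseline={
                "lam01_pre": [math.log(tr["lam01_pre"])],
                "lam02_pre": [math.log(tr["lam02_pre"])],
                "lam12_pre": [math.log(tr["lam12_pre"])],
                "lam01": [math.log(tr["lam01_pre"]) + divergence],
                "lam02": [math.log(tr["lam02_pre"])],
                "lam12": [math.log(tr["lam12_pre"])],
                "rho0": [math.log(tr["rho0"])],
                "rho1": [math.log(tr["rho1"])],
            }
        )
        analysis = MultistateModelSpec(
            n_states=3,
            transitions=((0, 1), (0, 2), (1, 2)),
            absorbing=frozenset({2}),
            baseline={(0, 1): "lam01", (0, 2): "lam02", (1, 2): "lam12"},
            state_names=("healthy", "ill", "dead"),
        )
        cfg = CohortSimConfig(
            name=name,
            n=800,
            spec=spec,
            true_params=params,
            seed=seed,
            visit=VisitSpec("exponential", {"mean": 0.8}),
            enrolment=EnrolmentSpec(
                kind="B",
                enrolled_states=(3, 4, 5),
                window=10.0,
                illness_state=1,
                illness_enrol_transition=(1, 4),
            ),
            censor_time=20.0,
            observed_state_map={3: 0, 4: 1, 5: 2},
            analysis_spec=analysis,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIO_NAMES}")
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg
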