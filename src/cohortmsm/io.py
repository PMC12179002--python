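"""Readers/writers: panel CSV, registry CSV, model and parameter configs.

CSV is the sole tabular interchange format; model specifications and
parameter vectors round-trip through a small versioned YAML schema.
Configs written by this module re-read to equal objects and re-write to
byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .joint import (
    RegistryRecord,
    build_fmt_model,
    build_illness_death_enrolment_model,
    build_psa_onset_model,
)
from .likelihood import FitResult, PanelDataset, relative_risk_table
from .model import MultistateModelSpec, ParameterVector, Term

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_registry_csv",
    "write_registry_csv",
    "spec_to_dict",
    "spec_from_dict",
    "read_model_config",
    "write_model_config",
    "params_to_dict",
    "params_from_dict",
    "read_params_config",
    "write_params_config",
    "fit_report",
]

_MODEL_SCHEMA = "cohortmsm-model-v1"
_PARAMS_SCHEMA = "cohortmsm-params-v1"

_TEMPLATES = {
    "psa_onset": build_psa_onset_model,
    "fmt8": build_fmt_model,
    "illness_death_enrolment": build_illness_death_enrolment_model,
}


# ---------------------------------------------------------------------------
# Panel / registry CSV
# ---------------------------------------------------------------------------

def read_panel_csv(path: str | Path, spec: MultistateModelSpec | None = None) -> PanelDataset:
    """Read a long-format panel CSV (subject_id, time, state, covariates...).

    Rows are normalized to time order within subject; structural
    problems (duplicate assessment times, non-monotone records, states
    outside the model space) raise with the offending subject named.
    """
    df = pd.read_csv(path)
    data = PanelDataset(df)
    if spec is not None:
        data.validate_for(spec)
    return data


def write_panel_csv(data: PanelDataset, path: str | Path) -> None:
    data.frame.to_csv(path, index=False)


def read_registry_csv(path: str | Path) -> list[RegistryRecord]:
    """Registry CSV: columns id, delta, time, then covariates."""
    df = pd.read_csv(path)
    for col in ("id", "delta", "time"):
        if col not in df.columns:
            raise ValueError(f"registry CSV missing column {col!r}")
    covs = [c for c in df.columns if c not in ("id", "delta", "time")]
    return [
        RegistryRecord(
            id=row["id"],
            delta=int(row["delta"]),
            time=float(row["time"]),
            covariates={c: float(row[c]) for c in covs},
        )
        for _, row in df.iterrows()
    ]


def write_registry_csv(records: Sequence[RegistryRecord] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, index=False)
        return
    rows = [{"id": r.id, "delta": r.delta, "time": r.time, **r.covariates} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Model spec config
# ---------------------------------------------------------------------------

def spec_to_dict(spec: MultistateModelSpec) -> dict:
    return {
        "schema": _MODEL_SCHEMA,
        "n_states": spec.n_states,
        "state_names": list(spec.state_names) if spec.state_names else None,
        "absorbing": sorted(spec.absorbing),
        "cutpoints": [float(c) for c in spec.cutpoints],
        "transitions": [
            {
                "from": k,
                "to": r,
                "baseline": spec.baseline[(k, r)],
                "design": [
                    {"coef": t.coef, "covariate": t.covariate, "scale": float(t.scale)}
                    for t in spec.design[(k, r)]
                ],
            }
            for k, r in spec.transitions
        ],
    }


def spec_from_dict(d: dict) -> MultistateModelSpec:
    if "template" in d:
        name = d["template"]
        if name not in _TEMPLATES:
            raise ValueError(f"unknown model template {name!r}; known: {sorted(_TEMPLATES)}")
        return _TEMPLATES[name](**d.get("options", {}))
    if d.get("schema") != _MODEL_SCHEMA:
        raise ValueError(f"unsupported model config schema {d.get('schema')!r}")
    transitions = tuple((t["from"], t["to"]) for t in d["transitions"])
    return MultistateModelSpec(
        n_states=int(d["n_states"]),
        transitions=transitions,
        absorbing=frozenset(d.get("absorbing", ())),
        cutpoints=tuple(d.get("cutpoints", ())),
        baseline={(t["from"], t["to"]): t["baseline"] for t in d["transitions"]},
        design={
            (t["from"], t["to"]): tuple(
                Term(coef=x["coef"], covariate=x.get("covariate"), scale=x.get("scale", 1.0))
                for x in t.get("design", ())
            )
            for t in d["transitions"]
        },
        state_names=tuple(d["state_names"]) if d.get("state_names") else None,
    )


def write_model_config(spec: MultistateModelSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec_to_dict(spec), sort_keys=False))


def read_model_config(path: str | Path) -> MultistateModelSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Parameter config
# ---------------------------------------------------------------------------

def params_to_dict(params: ParameterVector) -> dict:
    return {
        "schema": _PARAMS_SCHEMA,
        "log_baseline": {k: [float(x) for x in v] for k, v in params.log_baseline.items()},
        "coefficients": {k: float(v) for k, v in params.coefficients.items()},
    }


def params_from_dict(d: dict) -> ParameterVector:
    if d.get("schema") != _PARAMS_SCHEMA:
        raise ValueError(f"unsupported params config schema {d.get('schema')!r}")
    return ParameterVector(
        log_baseline={k: np.asarray(v, dtype=float) for k, v in d["log_baseline"].items()},
        coefficients=dict(d.get("coefficients", {})),
    )


def write_params_config(params: ParameterVector, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(params_to_dict(params), sort_keys=False))


def read_params_config(path: str | Path) -> ParameterVector:
    return params_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Fit report
# ---------------------------------------------------------------------------

def fit_report(fit: FitResult) -> str:
    """Human-readable fit summary: estimates, s.e., RR table, covariance."""
    buf = _io.StringIO()
    names = fit.parameter_names or fit.spec.parameter_names()
    se = fit.se
    print(f"log-likelihood: {fit.loglik:.6f}", file=buf)
    print(f"converged: {fit.converged} ({fit.message}; {fit.n_iter} iterations)", file=buf)
    print(f"subjects: {fit.n_subjects}, observation intervals: {fit.n_intervals}", file=buf)
    print("\nestimates:", file=buf)
    for n in names:
        print(f"  {n:<20s} {fit.estimate(n):>10.4f}  (s.e. {se[n]:.4f})", file=buf)
    if fit.spec.coefficient_names:
        print("\nrelative risks (exp(est), 95% Wald CI):", file=buf)
        rr = relative_risk_table(fit)
        for name, row in rr.iterrows():
            print(
                f"  {name:<20s} RR {row['rr']:.2f}  ({row['lo']:.2f}, {row['hi']:.2f})",
                file=buf,
            )
    if fit.covariance is not None:
        print("\ncovariance matrix:", file=buf)
        with np.printoptions(precision=6, suppress=True, linewidth=120):
            print(fit.covariance, file=buf)
    return buf.getvalue()
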