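"""Model specification schema, file formats, and run logs.

One declarative YAML/JSON schema covers the four kinds of model the package
simulates: a raw rate matrix, a factorized generative model, the
parameterized open enzymatic system, and a reaction network.  Loading
validates against the schema (unknown keys rejected with their location)
and round-trips losslessly through :func:`save_spec`.

Numeric text formats: rate matrices as delimited text with a header row of
state labels; trajectories as CSV with the time column first and full
double precision (17 significant digits), so repeated runs are
byte-comparable.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import generative, kinetics, network as network_mod
from .master import RateMatrix, Trajectory

__all__ = [
    "SpecError",
    "ModelSpec",
    "load_spec",
    "save_spec",
    "spec_to_rate_matrix",
    "spec_to_generative_model",
    "spec_to_enzymatic_system",
    "spec_to_network",
    "example_path",
    "read_rate_matrix",
    "write_rate_matrix",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "RunLog",
]


class SpecError(ValueError):
    """Schema violation, annotated with the offending location."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RateMatrixSpec(_Strict):
    labels: list[str]
    rows: list[list[float]]


class FactorSpec(_Strict):
    children: list[str]
    parents: list[str] = []
    table: Optional[list[list[float]]] = None
    alpha: Optional[float] = None

    @model_validator(mode="after")
    def _one_parameterization(self):
        if (self.table is None) == (self.alpha is None):
            raise ValueError("factor needs exactly one of 'table' or 'alpha'")
        return self


class ScaleSpec(_Strict):
    N: float = 1.0
    V: float = 1.0
    lam: float = 1.0


class EnzymaticSpec(_Strict):
    alpha1: float
    alpha2: float
    z: float
    c: float = 0.0


class ReactionSpec(_Strict):
    id: str
    kind: Literal["mass_action", "michaelis_menten"] = "mass_action"
    substrates: dict[str, int] = {}
    products: dict[str, int] = {}
    kf: Optional[float] = None
    kr: Optional[float] = None
    vmax: Optional[float] = None
    km: Optional[float] = None


class SimulationSpec(_Strict):
    t_max: float = 100.0
    n_points: int = 201
    initial: dict[str, float] = {}
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0
    horizon: float = 1e4


class ModelSpec(_Strict):
    """Top-level declarative model specification."""

    schema_version: int = 1
    kind: Literal["rate_matrix", "generative", "enzymatic", "network"]
    rate_matrix: Optional[RateMatrixSpec] = None
    species: list[str] = []
    factors: list[FactorSpec] = []
    lambdas: dict[str, float] = {}
    scale: ScaleSpec = ScaleSpec()
    enzymatic: Optional[EnzymaticSpec] = None
    reactions: list[ReactionSpec] = []
    sources: dict[str, float] = {}
    sensory: list[str] = []
    active: list[str] = []
    lesions: list[str] = []
    simulation: SimulationSpec = SimulationSpec()

    @model_validator(mode="after")
    def _kind_requirements(self):
        if self.kind == "rate_matrix" and self.rate_matrix is None:
            raise ValueError("kind 'rate_matrix' requires a rate_matrix block")
        if self.kind == "generative" and not self.factors:
            raise ValueError("kind 'generative' requires factors")
        if self.kind == "enzymatic" and self.enzymatic is None:
            raise ValueError("kind 'enzymatic' requires an enzymatic block")
        if self.kind == "network" and not self.reactions:
            raise ValueError("kind 'network' requires reactions")
        return self


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_spec(path: str | Path) -> ModelSpec:
    """Load and validate a YAML or JSON model specification."""
    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise SpecError(f"{path}: unparseable spec: {exc}") from exc
    if not isinstance(raw, dict):
        raise SpecError(f"{path}: spec must be a mapping, got {type(raw).__name__}")
    try:
        return ModelSpec.model_validate(raw)
    except ValidationError as exc:
        raise SpecError(f"{path}: {_format_validation_error(exc)}") from exc


def save_spec(spec: ModelSpec, path: str | Path) -> None:
    """Write a spec back to YAML or JSON; load(save(load(x))) == load(x)."""
    path = Path(path)
    data = spec.model_dump(exclude_none=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# spec -> domain objects
# ---------------------------------------------------------------------------


def spec_to_rate_matrix(spec: ModelSpec) -> RateMatrix:
    if spec.rate_matrix is None:
        raise SpecError("spec has no rate_matrix block")
    return RateMatrix(np.array(spec.rate_matrix.rows), labels=list(spec.rate_matrix.labels))


def _factor_from_spec(f: FactorSpec) -> generative.ConditionalFactor:
    if f.alpha is not None:
        if len(f.children) != 2 or f.parents:
            raise SpecError(
                "'alpha' shorthand requires exactly two children and no parents"
            )
        table = np.array([f.alpha, 0.0, 0.0, 1.0 - f.alpha])
    else:
        table = np.array(f.table)
    return generative.ConditionalFactor(
        children=list(f.children), parents=list(f.parents), table=table
    )


def spec_to_generative_model(spec: ModelSpec) -> generative.GenerativeModel:
    return generative.GenerativeModel(
        species=list(spec.species),
        factors=[_factor_from_spec(f) for f in spec.factors],
        lambdas=dict(spec.lambdas),
    )


def spec_to_scale(spec: ModelSpec) -> kinetics.ScaleParams:
    return kinetics.ScaleParams(N=spec.scale.N, V=spec.scale.V, lam=spec.scale.lam)


def spec_to_enzymatic_system(spec: ModelSpec) -> kinetics.EnzymaticSystem:
    if spec.enzymatic is None:
        raise SpecError("spec has no enzymatic block")
    e = spec.enzymatic
    return kinetics.EnzymaticSystem(
        alpha1=e.alpha1, alpha2=e.alpha2, z=e.z, c=e.c, scale=spec_to_scale(spec)
    )


def spec_to_network(spec: ModelSpec) -> network_mod.ReactionNetwork:
    raw = {
        "species": list(spec.species),
        "reactions": [
            {k: v for k, v in r.model_dump(exclude_none=True).items()}
            for r in spec.reactions
        ],
        "sources": dict(spec.sources),
        "sensory": list(spec.sensory),
        "active": list(spec.active),
    }
    return network_mod.assemble(raw)


def example_path(name: str) -> Path:
    """Path to a bundled example spec (fig1, fig3, fig5, fig6)."""
    p = Path(__file__).parent / "examples" / f"{name}.yaml"
    if not p.exists():
        raise FileNotFoundError(f"no bundled example named {name!r}")
    return p


# ---------------------------------------------------------------------------
# numeric text formats
# ---------------------------------------------------------------------------


def write_rate_matrix(L: RateMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Delimited numeric text with a header row of state labels."""
    labels = L.labels or [f"s{k}" for k in range(L.n_states)]
    lines = [delimiter.join(labels)]
    for row in L.entries:
        lines.append(delimiter.join(f"{v:.17g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rate_matrix(path: str | Path, delimiter: str = ",") -> RateMatrix:
    lines = Path(path).read_text().strip().splitlines()
    labels = [s.strip() for s in lines[0].split(delimiter)]
    rows = [[float(v) for v in ln.split(delimiter)] for ln in lines[1:]]
    return RateMatrix(np.array(rows), labels=labels)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """CSV: time column first, one column per state, optional free_energy.

    Full double precision so repeated deterministic runs produce identical
    bytes.
    """
    labels = traj.labels or [f"s{k}" for k in range(traj.states.shape[1])]
    df = pd.DataFrame(traj.states, columns=labels)
    df.insert(0, "time", traj.times)
    if traj.free_energy is not None:
        df["free_energy"] = traj.free_energy
    df.to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    fe = df.pop("free_energy").to_numpy() if "free_energy" in df.columns else None
    times = df.pop("time").to_numpy()
    return Trajectory(
        times=times,
        states=df.to_numpy(),
        labels=list(df.columns),
        free_energy=fe,
    )


# ---------------------------------------------------------------------------
# run logs
# ---------------------------------------------------------------------------


class RunLog:
    """Timestamped record of a CLI run: spec hash, solver settings,
    convergence diagnostics."""

    def __init__(self, spec_path: str | Path | None = None) -> None:
        self.records: dict = {
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "solver": {"method": "LSODA", "rtol": 1e-8, "atol": 1e-10},
        }
        if spec_path is not None:
            digest = hashlib.sha256(Path(spec_path).read_bytes()).hexdigest()
            self.records["spec"] = {"path": str(spec_path), "sha256": digest}

    def add(self, **kwargs) -> None:
        self.records.update(kwargs)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.records, indent=2, default=str))
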