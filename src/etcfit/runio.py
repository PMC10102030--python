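"""Run configuration and file round-tripping.

A run is described by one YAML file (mirrored by CLI flags; flags win)
naming the engine, its settings, the rate-law constants, the model and
dataset files, and — mandatorily — the random seed: there is no silent
nondeterminism.  The resolved configuration and its hash are echoed into
every run's metadata for provenance.

File formats owned elsewhere and re-exported here for convenience:
model JSON (:class:`etcfit.fba.ECModel`), dataset CSV
(:class:`etcfit.fitness.Dataset`), prior CSV
(:class:`etcfit.particles.PriorSpec`), history CSV + sidecar
(:class:`etcfit.history.RunHistory`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .de import DEConfig
from .fba import ECModel
from .fitness import Dataset, NGAMTable
from .history import RunHistory
from .particles import PriorSpec
from .ratelaw import RateLawConfig
from .smc import ABCConfig


@dataclass
class RunConfig:
    engine: str                       # "abc" | "de"
    model_path: str
    dataset_paths: list[str]
    prior_path: str
    seed: int
    output_dir: str = "run-output"
    withhold_chemostat: bool = False
    engine_options: dict = field(default_factory=dict)
    ratelaw_options: dict = field(default_factory=dict)
    ngam_points: list[list[float]] | None = None

    def __post_init__(self) -> None:
        if self.engine not in ("abc", "de"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")

    def validate_paths(self) -> None:
        for p in [self.model_path, self.prior_path, *self.dataset_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def ratelaw(self) -> RateLawConfig:
        return RateLawConfig(**self.ratelaw_options)

    def ngam(self) -> NGAMTable:
        if self.ngam_points is None:
            return NGAMTable()
        return NGAMTable(points=[tuple(p) for p in self.ngam_points])

    def engine_config(self):
        if self.engine == "abc":
            return ABCConfig(seed=self.seed, **self.engine_options)
        return DEConfig(seed=self.seed, **self.engine_options)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_meta(self) -> dict:
        meta = asdict(self)
        meta["config_hash"] = self.hash()
        return meta


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    cfg.validate_paths()
    return cfg


# -- convenience round-trips -------------------------------------------------

def load_model(path) -> ECModel:
    return ECModel.load(path)


def save_model(model: ECModel, path) -> None:
    model.save(path)


def load_datasets(path) -> list[Dataset]:
    return Dataset.list_from_frame(pd.read_csv(path))


def save_datasets(datasets, path) -> None:
    pd.concat([d.to_frame() for d in datasets]).to_csv(path, index=False)


def load_prior(path) -> PriorSpec:
    return PriorSpec.from_frame(pd.read_csv(path))


def save_prior(prior: PriorSpec, path) -> None:
    prior.to_frame().to_csv(path, index=False)


def save_history(history: RunHistory, directory) -> None:
    history.save(directory)


def load_history(directory) -> RunHistory:
    return RunHistory.load(directory)
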