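"""Run configuration and result serialisation.

A :class:`RunConfig` resolves command-line flags and/or a YAML file into a
single validated object with the study defaults filled in (4 chains, 2000
iterations, 1000 burn-in, 100 replicates, n = 1000).  Result writers embed
the package version, the resolved configuration and the master seed in every
output so any file can be regenerated from its own metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import MCMCConfig, PriorSpec

__all__ = ["RunConfig", "load_config", "write_results", "read_metrics"]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings of one run; every field has a documented default."""

    command: str = "grid"
    scenarios: str = "table1"
    data_path: str | None = None
    prior_mean: float | None = None
    prior_precision: list = field(default_factory=list)
    n_chains: int = 4
    n_iter: int = 2000
    n_burn: int = 1000
    reps: int = 100
    n: int = 1000
    seed: int = 0
    out: str | None = None
    intercept: bool = False
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.command not in ("simulate", "fit", "analyze", "grid"):
            raise ValueError(f"unknown command {self.command!r}")
        # delegate chain/burn-in validation
        MCMCConfig(n_chains=self.n_chains, n_iter=self.n_iter, n_burn=self.n_burn)
        if self.reps < 2:
            raise ValueError("reps must be >= 2")

    def mcmc(self, seed=None) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            n_burn=self.n_burn,
            seed=self.seed if seed is None else seed,
        )

    def priors(self) -> list[PriorSpec]:
        if self.prior_mean is None:
            raise ValueError("prior_mean is required to build priors")
        taus = self.prior_precision or [float(self.n), self.n / 10, self.n / 100]
        return [PriorSpec(mu_yz=self.prior_mean, tau_yz=float(t)) for t in taus]


def load_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Unknown keys are rejected by name; flag overrides win over file values.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**values)


def _metadata(config: RunConfig | None, seed) -> dict:
    return {
        "version": __version__,
        "seed": seed,
        "config": dataclasses.asdict(config) if config is not None else None,
    }


def write_results(obj, path, config: RunConfig | None = None, seed=None) -> Path:
    """Write a metrics table (CSV) or a fit summary (JSON) with embedded metadata.

    CSV bodies are deterministic for a given config and seed; the metadata
    travels in a ``.meta.json`` sidecar next to the table so the CSV itself
    stays byte-reproducible.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
            sidecar = path.with_suffix(path.suffix + ".meta.json")
            sidecar.write_text(json.dumps(_metadata(config, seed), indent=2))
        else:
            payload = dict(obj) if isinstance(obj, dict) else dataclasses.asdict(obj)
            payload["_meta"] = _metadata(config, seed)
            path.write_text(json.dumps(payload, indent=2, default=_jsonify))
    except OSError as exc:
        raise OSError(f"failed to write results to {path}: {exc}") from exc
    return path


def _jsonify(value):
    import numpy as np

    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    raise TypeError(f"not JSON serialisable: {type(value)}")


def read_metrics(path) -> pd.DataFrame:
    """Round-trip reader for metric tables written by :func:`write_results`."""
    return pd.read_csv(path)
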