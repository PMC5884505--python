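"""Pipeline configuration: one YAML/JSON-serialisable object holding the
b-value scheme, fit constraints, relaxation constants, phantom design, MCMC
settings, seeds and evaluation options. Every default matches the package's
documented study conditions, so an empty config is a valid run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .bayes import MCMCConfig
from .fitters import FitConstraints
from .model import BValueScheme, RelaxationConstants
from .synthetic import PhantomSpec, TissueRanges

__all__ = ["PipelineConfig", "ALGORITHM_NAMES"]

#: the six fit algorithms, by CLI name.
ALGORITHM_NAMES = ("free", "fixed", "adaptive", "mle", "bayes-lin", "bayes-log")


def _tuplify(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()}


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    scheme: BValueScheme = field(default_factory=BValueScheme)
    constraints: FitConstraints = field(default_factory=FitConstraints)
    relaxation: RelaxationConstants = field(default_factory=RelaxationConstants)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    algorithms: tuple[str, ...] = ALGORITHM_NAMES
    mu_mode: str = "population"
    seed: int = 0

    def __post_init__(self) -> None:
        self.algorithms = tuple(self.algorithms)
        unknown = set(self.algorithms) - set(ALGORITHM_NAMES)
        if unknown:
            raise ValueError(
                f"unknown fitter name(s) {sorted(unknown)}; valid: {ALGORITHM_NAMES}"
            )
        if self.mu_mode not in ("population", "per_subject"):
            raise ValueError("mu_mode must be 'population' or 'per_subject'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scheme"] = {
            "b_values": self.scheme.b_values.tolist(),
            "n_directions": self.scheme.n_directions.tolist(),
        }
        d["algorithms"] = list(self.algorithms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict = {}
        if "phantom" in d:
            ph = dict(d.pop("phantom"))
            for tissue in ("tumour", "normal"):
                if tissue in ph and isinstance(ph[tissue], dict):
                    ph[tissue] = TissueRanges(**_tuplify(ph[tissue], ("f", "D", "Dstar")))
            kwargs["phantom"] = PhantomSpec(**ph)
        if "scheme" in d:
            sc = d.pop("scheme")
            kwargs["scheme"] = BValueScheme(sc["b_values"], sc["n_directions"])
        if "constraints" in d:
            kwargs["constraints"] = FitConstraints(
                **_tuplify(dict(d.pop("constraints")), ("D_bounds", "Dstar_bounds", "f_bounds"))
            )
        if "relaxation" in d:
            kwargs["relaxation"] = RelaxationConstants(**d.pop("relaxation"))
        if "mcmc" in d:
            kwargs["mcmc"] = MCMCConfig(**d.pop("mcmc"))
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
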