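"""Study configuration: one YAML document, explicit named seeds."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .dataset import NoiseConfig
from .errors import InvalidParameterError
from .population import ParamSpec, SamplingConfig
from .regression import DEFAULT_GRIDS, CVConfig
from .simulator import SolverConfig

__all__ = ["StudyConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce the study end to end."""

    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    grids: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_GRIDS.items()
    })
    targets: tuple[str, ...] = ("aSBP", "CO", "E_es")
    apply_noise: bool = True
    batch_size: int = 128
    output_dir: str = "results"

    def config_hash(self) -> str:
        """Stable short hash recorded in every output's provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sampling"]["params"] = {
            k: asdict(v) if isinstance(v, ParamSpec) else v
            for k, v in self.sampling.params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        sampling = d.pop("sampling", {})
        if "params" in sampling:
            sampling["params"] = {
                k: ParamSpec(**v) for k, v in sampling["params"].items()
            }
        try:
            return cls(
                sampling=SamplingConfig(**sampling),
                solver=SolverConfig(**d.pop("solver", {})),
                noise=NoiseConfig(**d.pop("noise", {})),
                cv=CVConfig(**d.pop("cv", {})),
                **{k: tuple(v) if k == "targets" else v for k, v in d.items()},
            )
        except TypeError as exc:
            raise InvalidParameterError(str(exc)) from exc

    def with_seed_offset(self, offset: int) -> "StudyConfig":
        """Shift every named seed by a common offset (CLI --seed-override)."""
        return replace(
            self,
            sampling=replace(self.sampling, seed=self.sampling.seed + offset),
            noise=replace(self.noise, seed=self.noise.seed + offset),
            cv=replace(self.cv, seed=self.cv.seed + offset),
        )


def load_config(path: str | Path | None) -> StudyConfig:
    if path is None:
        return StudyConfig()
    with open(path) as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
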