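"""Virtual-population sampling.

Eight physiological parameters are drawn independently from truncated
Gaussians (truncation by rejection-resampling, so no probability mass piles
up at the bounds); dead volume and time-to-peak elastance are fixed
constants.  The default distribution table is the study population
(n = 4,018); an alternate config carries the wider textbook ranges quoted in
prose (HR 60-100, TPR 0.5-2.0, D_ao 1.9-4.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError
from .simulator import ArterialParams, CardiacParams, VirtualSubject

__all__ = [
    "ParamSpec",
    "SamplingConfig",
    "DEFAULT_SAMPLING",
    "METHODS_RANGE_SAMPLING",
    "sample_population",
    "validate_subject",
    "truncated_gaussian_mean",
]


@dataclass(frozen=True)
class ParamSpec:
    """Truncated-Gaussian marginal for one parameter."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min < self.max):
            raise InvalidParameterError(
                f"infeasible truncation: min={self.min} >= max={self.max}"
            )
        if self.sd <= 0:
            raise InvalidParameterError(f"sd must be positive, got {self.sd}")


#: Population marginals: mean, SD, min, max per sampled parameter.
_TABLE = {
    "e_es": ParamSpec(2.29, 0.40, 1.03, 3.50),      # mmHg/mL
    "e_ed": ParamSpec(0.12, 0.09, 0.05, 0.20),      # mmHg/mL
    "p_fill": ParamSpec(15.12, 2.10, 7.00, 23.00),  # mmHg
    "tac": ParamSpec(1.86, 0.90, 0.10, 3.80),       # mL/mmHg
    "tpr": ParamSpec(0.80, 0.19, 0.50, 1.30),       # mmHg s/mL
    "hr": ParamSpec(82.57, 8.15, 61.10, 110.00),    # bpm
    "d_ao": ParamSpec(3.00, 1.00, 2.00, 4.00),      # cm
    "height": ParamSpec(175.00, 25.00, 150.00, 200.00),  # cm
}

PARAM_NAMES = tuple(_TABLE)


@dataclass(frozen=True)
class SamplingConfig:
    """Population size, seed, fixed constants and per-parameter marginals."""

    n: int = 4018
    seed: int = 0
    v_d: float = 15.0       # mL, fixed
    t_max: float = 0.340    # s, fixed
    params: dict[str, ParamSpec] = field(default_factory=lambda: dict(_TABLE))

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidParameterError(f"population size must be >= 0, got {self.n}")
        missing = set(PARAM_NAMES) - set(self.params)
        if missing:
            raise InvalidParameterError(f"missing parameter specs: {sorted(missing)}")


DEFAULT_SAMPLING = SamplingConfig()

#: The wider prose ranges (same means/SDs); not used by the default study.
METHODS_RANGE_SAMPLING = replace(
    DEFAULT_SAMPLING,
    params={
        **_TABLE,
        "hr": ParamSpec(82.57, 8.15, 60.0, 100.0),
        "tpr": ParamSpec(0.80, 0.19, 0.50, 2.00),
        "d_ao": ParamSpec(3.00, 1.00, 1.90, 4.00),
    },
)


def _sample_truncated(rng: np.random.Generator, spec: ParamSpec, n: int) -> np.ndarray:
    """Gaussian draws, resampled (not clipped) until inside [min, max]."""
    out = rng.normal(spec.mean, spec.sd, size=n)
    bad = (out < spec.min) | (out > spec.max)
    while np.any(bad):
        out[bad] = rng.normal(spec.mean, spec.sd, size=int(bad.sum()))
        bad = (out < spec.min) | (out > spec.max)
    return out


def sample_population(config: SamplingConfig = DEFAULT_SAMPLING) -> list[VirtualSubject]:
    """Draw ``config.n`` independent virtual subjects (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    draws = {name: _sample_truncated(rng, config.params[name], config.n)
             for name in PARAM_NAMES}
    subjects = []
    for i in range(config.n):
        cardiac = CardiacParams(
            e_es=float(draws["e_es"][i]),
            e_ed=float(draws["e_ed"][i]),
            p_fill=float(draws["p_fill"][i]),
            hr=float(draws["hr"][i]),
            v_d=config.v_d,
            t_max=config.t_max,
        )
        arterial = ArterialParams(
            d_ao=float(draws["d_ao"][i]),
            height=float(draws["height"][i]),
            tac=float(draws["tac"][i]),
            tpr=float(draws["tpr"][i]),
        )
        subjects.append(VirtualSubject(cardiac, arterial, id=f"s{i:05d}"))
    return subjects


_FIELD_OF = {
    "e_es": ("cardiac", "e_es"), "e_ed": ("cardiac", "e_ed"),
    "p_fill": ("cardiac", "p_fill"), "hr": ("cardiac", "hr"),
    "tac": ("arterial", "tac"), "tpr": ("arterial", "tpr"),
    "d_ao": ("arterial", "d_ao"), "height": ("arterial", "height"),
}


def validate_subject(subject: VirtualSubject,
                     config: SamplingConfig = DEFAULT_SAMPLING) -> list[str]:
    """Diagnostic bound/invariant check; returns a list of violations."""
    violations = []
    for name, (block, attr) in _FIELD_OF.items():
        value = getattr(getattr(subject, block), attr)
        spec = config.params[name]
        if not (spec.min <= value <= spec.max):
            violations.append(
                f"{name}={value:.4g} outside [{spec.min}, {spec.max}]"
            )
    if not (subject.cardiac.e_es > subject.cardiac.e_ed):
        violations.append(
            f"E_es={subject.cardiac.e_es:.4g} not greater than "
            f"E_ed={subject.cardiac.e_ed:.4g}"
        )
    return violations


def truncated_gaussian_mean(spec: ParamSpec) -> float:
    """Exact mean of the truncated Gaussian (scipy closed form); used as an
    independent check of the rejection sampler."""
    from scipy.stats import truncnorm

    a = (spec.min - spec.mean) / spec.sd
    b = (spec.max - spec.mean) / spec.sd
    return float(truncnorm.mean(a, b, loc=spec.mean, scale=spec.sd))
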