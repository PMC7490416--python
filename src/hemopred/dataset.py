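"""Study-dataset assembly, noise corruption and CSV serialisation.

One row per retained subject with the canonical column layout
``subject_id, brSBP_mmHg, brDBP_mmHg, HR_bpm, cfPWV_mps, EF_pct, aSBP_mmHg,
CO_Lmin, Ees_mmHg_per_mL``.  Measurement noise is a bounded relative error:
every feature and target cell is multiplied by (1 + eps) with eps drawn from
a truncated Gaussian (sd ``sigma_rel``, resampled into [-max_rel, +max_rel];
a bounded-uniform alternative is available).  Provenance (seeds, simulator
version) travels in a JSON sidecar next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .measurements import FeatureRecord, TargetRecord

__all__ = [
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "NoiseConfig",
    "StudyDataset",
    "assemble_dataset",
    "corrupt",
    "write_dataset",
    "read_dataset",
]

#: Short feature/target names -> canonical CSV column headers.
FEATURE_COLUMNS = {
    "brSBP": "brSBP_mmHg",
    "brDBP": "brDBP_mmHg",
    "HR": "HR_bpm",
    "cfPWV": "cfPWV_mps",
    "EF": "EF_pct",
}
TARGET_COLUMNS = {
    "aSBP": "aSBP_mmHg",
    "CO": "CO_Lmin",
    "E_es": "Ees_mmHg_per_mL",
}
ALL_COLUMNS = ["subject_id", *FEATURE_COLUMNS.values(), *TARGET_COLUMNS.values()]


@dataclass(frozen=True)
class NoiseConfig:
    """Bounded relative measurement error applied to every numeric cell."""

    max_rel: float = 0.06
    sigma_rel: float = 0.02
    seed: int = 0
    distribution: str = "truncated_gaussian"   # or "uniform"

    def __post_init__(self) -> None:
        if self.max_rel < 0 or self.sigma_rel < 0:
            raise InvalidParameterError("noise magnitudes must be >= 0")
        if self.sigma_rel > self.max_rel:
            raise InvalidParameterError(
                f"sigma_rel={self.sigma_rel} exceeds max_rel={self.max_rel}"
            )
        if self.distribution not in ("truncated_gaussian", "uniform"):
            raise InvalidParameterError(
                f"unknown noise distribution {self.distribution!r}"
            )


@dataclass
class StudyDataset:
    """The regression table plus its provenance block."""

    table: pd.DataFrame
    provenance: dict

    @property
    def n(self) -> int:
        return len(self.table)


def assemble_dataset(records: list[tuple[str, FeatureRecord, TargetRecord]],
                     provenance: dict | None = None) -> StudyDataset:
    """Build the study table from (subject_id, features, targets) triples."""
    rows = [
        {
            "subject_id": sid,
            "brSBP_mmHg": f.br_sbp,
            "brDBP_mmHg": f.br_dbp,
            "HR_bpm": f.hr,
            "cfPWV_mps": f.cf_pwv,
            "EF_pct": 100.0 * f.ef,
            "aSBP_mmHg": t.a_sbp,
            "CO_Lmin": t.co,
            "Ees_mmHg_per_mL": t.e_es,
        }
        for sid, f, t in records
    ]
    table = pd.DataFrame(rows, columns=ALL_COLUMNS)
    return StudyDataset(table=table, provenance=dict(provenance or {}))


def _draw_noise(rng: np.random.Generator, noise: NoiseConfig, shape) -> np.ndarray:
    if noise.distribution == "uniform":
        return rng.uniform(-noise.max_rel, noise.max_rel, size=shape)
    if noise.sigma_rel == 0:
        return np.zeros(shape)
    eps = rng.normal(0.0, noise.sigma_rel, size=shape)
    bad = np.abs(eps) > noise.max_rel
    while np.any(bad):
        eps[bad] = rng.normal(0.0, noise.sigma_rel, size=int(bad.sum()))
        bad = np.abs(eps) > noise.max_rel
    return eps


def corrupt(dataset: StudyDataset, noise: NoiseConfig) -> StudyDataset:
    """Return a noise-corrupted copy: x -> x * (1 + eps) per numeric cell."""
    rng = np.random.default_rng(noise.seed)
    table = dataset.table.copy()
    cols = [c for c in ALL_COLUMNS if c != "subject_id" and c in table.columns]
    eps = _draw_noise(rng, noise, (len(table), len(cols)))
    table[cols] = table[cols].to_numpy() * (1.0 + eps)
    prov = dict(dataset.provenance)
    prov["noise"] = asdict(noise)
    return StudyDataset(table=table, provenance=prov)


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """CSV plus a ``<path>.meta.json`` provenance sidecar."""
    path = Path(path)
    dataset.table.to_csv(path, index=False, float_format="%.12g")
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(dataset.provenance, indent=2, default=str)
    )


def read_dataset(path: str | Path, require_targets: bool = False) -> StudyDataset:
    """Read a study or external (features-only) CSV.

    The five feature columns are mandatory; target columns may be absent in
    external tables unless ``require_targets`` is set.  Raises FormatError
    naming the first missing column.
    """
    path = Path(path)
    table = pd.read_csv(path)
    required = ["subject_id", *FEATURE_COLUMNS.values()]
    if require_targets:
        required += list(TARGET_COLUMNS.values())
    for col in required:
        if col not in table.columns:
            raise FormatError(f"missing required column: {col}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    provenance = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return StudyDataset(table=table, provenance=provenance)
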