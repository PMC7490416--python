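"""Feature and target extraction from simulated waveforms.

Noninvasive features: brachial SBP/DBP (trace extrema), heart rate, the
carotid-femoral pulse wave velocity from the intersecting-tangents (foot-to-
foot) method, and ejection fraction from the LV volume trace.  Invasive
targets: aortic systolic pressure (root trace maximum), cardiac output
(SV x HR) and the subject's ground-truth end-systolic elastance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ExtractionError, FootDetectionError, PreconditionError, TransitError
from .simulator import SimulationResult, VirtualSubject

__all__ = [
    "FeatureRecord",
    "TargetRecord",
    "extract_pressure_extrema",
    "detect_wave_foot",
    "compute_cfpwv",
    "compute_cardiac_outputs",
    "build_record",
]


@dataclass(frozen=True)
class FeatureRecord:
    """The five noninvasive inputs (EF stored as a fraction in (0, 1))."""

    br_sbp: float   # mmHg
    br_dbp: float   # mmHg
    hr: float       # bpm
    cf_pwv: float   # m/s
    ef: float       # fraction

    def __post_init__(self) -> None:
        if not (self.br_sbp > self.br_dbp):
            raise ExtractionError(
                f"brSBP={self.br_sbp:.2f} must exceed brDBP={self.br_dbp:.2f}"
            )
        if self.cf_pwv <= 0:
            raise ExtractionError(f"cfPWV must be positive, got {self.cf_pwv}")
        if not (0.0 < self.ef < 1.0):
            raise ExtractionError(f"EF={self.ef:.3f} outside (0, 1)")


@dataclass(frozen=True)
class TargetRecord:
    """The three invasive outputs (E_es is the sampled ground truth)."""

    a_sbp: float    # mmHg
    co: float       # L/min
    e_es: float     # mmHg/mL

    def __post_init__(self) -> None:
        if min(self.a_sbp, self.co, self.e_es) <= 0:
            raise ExtractionError("targets must be positive")


def extract_pressure_extrema(wave: np.ndarray) -> tuple[float, float]:
    """(SBP, DBP) = (max, min) of one pressure cycle."""
    wave = np.asarray(wave, dtype=float)
    if wave.size == 0:
        raise PreconditionError("empty pressure trace")
    return float(wave.max()), float(wave.min())


def detect_wave_foot(wave: np.ndarray, t: np.ndarray) -> float:
    """Wave-foot time by the intersecting-tangents method.

    The upstroke tangent passes through the point of maximum first
    derivative (central differences); the foot is its intersection with the
    horizontal line through the cycle minimum preceding the upstroke.
    """
    wave = np.asarray(wave, dtype=float)
    t = np.asarray(t, dtype=float)
    if wave.size < 3 or wave.size != t.size:
        raise PreconditionError("need aligned traces with >= 3 samples")
    # the systolic upstroke is the steepest rise before the cycle maximum
    # (later rises, e.g. after a deep dicrotic notch, are not the foot)
    i_pk = int(np.argmax(wave))
    if i_pk < 2:
        raise FootDetectionError("cycle maximum at the trace start")
    dp = np.gradient(wave, t)
    i_up = int(np.argmax(dp[: i_pk + 1]))
    slope = float(dp[i_up])
    if slope <= 0:
        raise FootDetectionError("no positive systolic upstroke found")
    p_min = float(wave[: i_up + 1].min())
    return float(t[i_up] - (wave[i_up] - p_min) / slope)


def compute_cfpwv(carotid: np.ndarray, femoral: np.ndarray,
                  t: np.ndarray, path_length: float) -> float:
    """Carotid-femoral PWV: path length / foot-to-foot transit time (m/s)."""
    t_car = detect_wave_foot(carotid, t)
    t_fem = detect_wave_foot(femoral, t)
    transit = t_fem - t_car
    if transit <= 0:
        raise TransitError(
            f"non-positive carotid-femoral transit time ({transit * 1e3:.2f} ms)"
        )
    return float(path_length / transit)


def compute_cardiac_outputs(v_lv: np.ndarray, hr: float
                            ) -> tuple[float, float, float, float, float]:
    """(SV mL, EDV mL, ESV mL, EF %, CO L/min) from one LV volume cycle."""
    v_lv = np.asarray(v_lv, dtype=float)
    if v_lv.size == 0:
        raise PreconditionError("empty volume trace")
    edv = float(v_lv.max())
    esv = float(v_lv.min())
    if edv <= esv:
        raise ExtractionError("EDV must exceed ESV over a full cycle")
    sv = edv - esv
    ef = sv / edv
    co = sv * hr / 1000.0
    return sv, edv, esv, 100.0 * ef, co


def build_record(result: SimulationResult, subject: VirtualSubject
                 ) -> tuple[FeatureRecord, TargetRecord]:
    """Assemble one subject's feature/target rows from a converged run.

    HR and E_es are copied from the subject (HR is set, E_es is the ground
    truth the regression study tries to recover).  Raises ExtractionError
    (or a subclass of HemopredError) when the subject must be dropped.
    """
    if not result.converged:
        raise ExtractionError("simulation did not reach periodic steady state")
    br_sbp, br_dbp = extract_pressure_extrema(result.p_site["brachial"])
    a_sbp, _ = extract_pressure_extrema(result.p_site["aortic_root"])
    cf_pwv = compute_cfpwv(
        result.p_site["carotid"], result.p_site["femoral"],
        result.t, result.cf_path_length,
    )
    _, _, _, ef_pct, co = compute_cardiac_outputs(result.v_lv, subject.cardiac.hr)
    features = FeatureRecord(
        br_sbp=br_sbp, br_dbp=br_dbp, hr=subject.cardiac.hr,
        cf_pwv=cf_pwv, ef=ef_pct / 100.0,
    )
    targets = TargetRecord(a_sbp=a_sbp, co=co, e_es=subject.cardiac.e_es)
    return features, targets
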