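"""Frozen arterial-tree template.

The tree is a reduced transmission-line network covering the segments needed
for the four measurement sites (aortic root, brachial, carotid, femoral):
ascending aorta -> arch -> thoracic -> abdominal aorta -> iliac -> femoral
trunk, with the carotid and subclavian->brachial branches leaving the arch
and two lumped side beds (splanchnic/renal and pelvic/contralateral-leg)
carrying the remaining flow.  Each segment is discretised into >= 4 RLC
sub-elements so that wave-foot transit times are resolved.

Segment lengths are stated for a 175 cm subject and scale linearly with
height; diameters are fixed ratios of the aortic root diameter.  Local pulse
wave velocity follows an inverse power law of lumen diameter,
``PWV = a * d**-b``; per-length compliance follows Bramwell-Hill.  The
fraction of total arterial compliance held by the tree itself (the rest sits
in the terminal Windkessels) is ``TREE_COMPLIANCE_REF`` at the reference TAC
and scales as ``(TAC/REF_TAC)**TREE_COMPLIANCE_EXP``; both constants were
frozen by the scripted calibration in ``analysis/00_calibrate_template.py``
against the target population cfPWV distribution (mean ~8.9 m/s, range
~[5.5, 14.3] m/s).
"""

from __future__ import annotations

from dataclasses import dataclass

# -- physical constants (CGS unless noted) ---------------------------------
MMHG_CGS = 1333.22      # dyn cm^-2 per mmHg
RHO = 1.05              # blood density, g cm^-3
MU = 0.04               # blood viscosity, g cm^-1 s^-1 (4 mPa s)

REF_HEIGHT = 175.0      # cm, template scale
REF_DIAMETER = 3.0      # cm, reference aortic root diameter for branches
P_VENOUS = 15.0         # mmHg, fixed venous outflow pressure of the beds
REF_TAC = 1.86          # mL/mmHg, population mean total arterial compliance

# -- wave-speed / compliance calibration (frozen; see module docstring) -----
PWV_EXPONENT = 0.5          # b in PWV = a * d**-b
PWV_COEFF = 10.0            # a, m s^-1 cm^b; nominal raw-law coefficient
TREE_COMPLIANCE_REF = 0.582  # mL/mmHg held by the tree at REF_TAC (calibrated)
TREE_COMPLIANCE_EXP = 1.0   # gamma: C_tree = REF * (C_eff/REF_TAC)**gamma
TREE_COMPLIANCE_CAP = 0.9   # tree never holds more than this fraction of TAC
TREE_GEOMETRY_EXP = 1.0     # phi: C_tree scales with (raw-law geometry)^phi

# -- effective-parameter maps (nonlinearity emulation; frozen) --------------
# The reference tree has pressure-dependent (stiffening) walls and an
# exponential diastolic pressure-volume relation.  A linear surrogate fed
# the raw sampled parameters over their full ranges produces far wider
# hemodynamic spreads than the reference population tables (e.g. a 38-fold
# sampled compliance range versus the ~7-fold realized stiffness range
# implied by the printed cfPWV bounds).  These compressive maps reproduce
# the realized operating ranges; each map is the identity at the
# population-mean value.
TAC_EFFECTIVE_EXP = 0.55    # C_eff = REF_TAC*(TAC/REF_TAC)**0.55
ROOT_DIAMETER_EXP = 0.15    # trunk calibre = REF_D*(D_ao/REF_D)**0.15
EED_EFFECTIVE_EXP = 0.5     # diastolic stiffness = REF_EED*(E_ed/REF_EED)**0.5
REF_EED = 0.12              # mmHg/mL, population-mean end-diastolic elastance

# -- lumped valve / terminal parameterisation ------------------------------
R_AORTIC_VALVE = 0.01       # mmHg s/mL, aortic valve series resistance
R_MITRAL_VALVE = 0.020      # mmHg s/mL, mitral series resistance (calibrated)
# Windkessel characteristic impedance: terminals that end a single narrow
# limb (the measured carotid/brachial/femoral vessels) are matched to the
# feeding segment's transmission-line impedance sqrt(L/C) (capped at half
# the terminal resistance) so high-frequency energy is absorbed instead of
# reflecting with inverted sign at the measurement site; lumped central
# beds (many parallel vessels, low collective impedance) use a small
# fixed fraction of their terminal resistance.
TERMINAL_ZC_RCAP = 0.5
TERMINAL_ZC_FRAC = 0.05
TERMINAL_R_TOL = 1e-6       # relative tolerance of the TPR calibration
# Voigt (Kelvin) viscoelastic wall: each wall compliance carries a series
# resistance R_w = WALL_VISC_TAU / C.  This damps the otherwise nearly
# lossless inertial sloshing between the tree and the terminal reservoirs
# (purely elastic walls ring at a few Hz, which real arteries do not).
WALL_VISC_TAU = 0.0004      # s
ELEMENT_LENGTH = 5.0        # cm, target RLC element length
MIN_ELEMENTS = 4            # minimum sub-elements per segment


@dataclass(frozen=True)
class SegmentSpec:
    """One template segment (lengths at 175 cm height, diameters vs D_ao)."""

    name: str
    parent: str | None
    length: float          # cm
    diam_ratio: float      # lumen diameter / aortic root diameter
    terminal_frac: float | None = None   # share of cardiac output if leaf
    zc_matched: bool = False             # match WK Zc to the feeding tube
    compliance_frac: float | None = None  # share of terminal compliance
    compliance_boost: float = 1.0        # weight vs the pure diameter law
    visc_tau: float | None = None        # segment wall time constant override
    scales_with_root: bool = False       # diameter follows D_ao (aortic trunk)
    diam_ratio_start: float | None = None  # inlet ratio for tapered segments


#: Topology, geometry and flow split of the reduced tree (frozen).
SEGMENTS: tuple[SegmentSpec, ...] = (
    SegmentSpec("ascending_aorta", None, 5.0, 0.96,
                scales_with_root=True, diam_ratio_start=1.00,
                compliance_boost=4.0),
    SegmentSpec("aortic_arch_a", "ascending_aorta", 3.0, 0.92,
                scales_with_root=True, diam_ratio_start=0.96,
                compliance_boost=3.0),
    SegmentSpec("carotid", "aortic_arch_a", 17.0, 0.20, terminal_frac=0.15,
                zc_matched=True, compliance_frac=0.05, compliance_boost=2.0,
                diam_ratio_start=0.24),
    SegmentSpec("aortic_arch_b", "aortic_arch_a", 3.0, 0.82,
                scales_with_root=True, diam_ratio_start=0.92,
                compliance_boost=3.0),
    SegmentSpec("subclavian", "aortic_arch_b", 7.0, 0.28,
                compliance_boost=3.0, visc_tau=0.006, diam_ratio_start=0.32),
    SegmentSpec("brachial", "subclavian", 42.0, 0.12, terminal_frac=0.02,
                zc_matched=True, compliance_frac=0.01, compliance_boost=3.0,
                visc_tau=0.006, diam_ratio_start=0.28),
    SegmentSpec("thoracic_aorta", "aortic_arch_b", 18.0, 0.62,
                scales_with_root=True, diam_ratio_start=0.82),
    SegmentSpec("splanchnic", "thoracic_aorta", 8.0, 0.50, terminal_frac=0.53,
                compliance_frac=0.55, compliance_boost=6.0,
                diam_ratio_start=0.50),
    SegmentSpec("abdominal_aorta", "thoracic_aorta", 16.0, 0.42,
                scales_with_root=True, diam_ratio_start=0.62),
    SegmentSpec("pelvic", "abdominal_aorta", 4.0, 0.45, terminal_frac=0.15,
                compliance_frac=0.20, compliance_boost=6.0,
                diam_ratio_start=0.45),
    SegmentSpec("iliac", "abdominal_aorta", 7.0, 0.34,
                diam_ratio_start=0.42),
    SegmentSpec("femoral", "iliac", 28.0, 0.24, terminal_frac=0.15,
                zc_matched=True, compliance_frac=0.18, compliance_boost=6.0,
                diam_ratio_start=0.32),
)

#: Measurement sites: segment name and relative position along it (0=inlet).
MEASUREMENT_SITES: dict[str, tuple[str, float]] = {
    "aortic_root": ("ascending_aorta", 0.0),
    "carotid": ("carotid", 1.0),
    "brachial": ("brachial", 1.0),
    "femoral": ("femoral", 1.0),
}

#: Segments on the arch->femoral-site limb of the carotid-femoral path.
CF_AORTIC_LIMB = ("aortic_arch_b", "thoracic_aorta", "abdominal_aorta",
                  "iliac", "femoral")
#: Segment carrying the carotid limb (site at its distal end).
CF_CAROTID_LIMB = ("carotid",)


def cf_path_length(height: float) -> float:
    """Carotid-femoral path length in metres for a subject of given height.

    Transit time is the difference of foot arrival times of two waves that
    share the root->arch course, so the effective path is the difference of
    the two non-common limbs (arch->femoral site minus arch->carotid site),
    scaled linearly with body height.
    """
    by_name = {s.name: s for s in SEGMENTS}
    aortic = sum(by_name[n].length for n in CF_AORTIC_LIMB)
    carotid = sum(by_name[n].length for n in CF_CAROTID_LIMB)
    return (aortic - carotid) * (height / REF_HEIGHT) / 100.0
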