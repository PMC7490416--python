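"""Reduced-order lumped cardiovascular simulator.

A time-varying elastance left ventricle (linear ESPVR with slope ``E_es``
and dead volume ``V_d``, linear EDPVR with slope ``E_ed``) ejects through an
ideal-diode aortic valve into a transmission-line arterial tree built from
the frozen template (:mod:`hemopred.template`).  Every tree segment is a
ladder of RLC sub-elements (series viscous resistance and blood inertance,
shunt wall compliance); each leaf terminates in a three-element Windkessel.
Filling comes from a constant venous pressure source through an ideal-diode
mitral valve.

The arterial network is linear and time-invariant, so one implicit
theta-scheme step (theta = 0.6 by default: close to trapezoidal for low
numerical dissipation, with enough upwinding to damp valve-closure
ringing) is a single multiply with precomputed matrices; the nonlinear
LV/valve corner is folded in exactly through a scalar Schur complement at
the root node.  The scheme is A-stable and deterministic at a fixed
0.5 ms step.  Subjects are integrated in batches
(stacked matrices) for throughput; results are bitwise independent of batch
composition because every subject owns its system matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import template as tpl
from .errors import InvalidParameterError, PreconditionError, SimulationFailureError

__all__ = [
    "CardiacParams",
    "ArterialParams",
    "VirtualSubject",
    "ArterialTree",
    "SimulationResult",
    "SolverConfig",
    "normalized_activation",
    "elastance_at",
    "build_arterial_tree",
    "simulate_beat",
    "simulate_population",
    "steady_state_error",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CardiacParams:
    """Left-ventricular parameters of one subject.

    Units: elastances mmHg/mL, volumes mL, times s, pressures mmHg, HR bpm.
    """

    e_es: float
    e_ed: float
    p_fill: float
    hr: float
    v_d: float = 15.0
    t_max: float = 0.340

    def __post_init__(self) -> None:
        if not (self.e_es > self.e_ed > 0):
            raise InvalidParameterError(
                f"need E_es > E_ed > 0, got E_es={self.e_es}, E_ed={self.e_ed}"
            )
        if self.v_d < 0:
            raise InvalidParameterError(f"V_d must be >= 0, got {self.v_d}")
        if self.hr <= 0:
            raise InvalidParameterError(f"HR must be positive, got {self.hr}")
        if not (0 < self.t_max < 60.0 / self.hr):
            raise InvalidParameterError(
                f"t_max={self.t_max} must lie in (0, {60.0 / self.hr:.3f}) s"
            )
        if self.p_fill <= 0:
            raise InvalidParameterError(f"P_fill must be positive, got {self.p_fill}")

    @property
    def period(self) -> float:
        return 60.0 / self.hr


@dataclass(frozen=True)
class ArterialParams:
    """Arterial geometry and lumped afterload of one subject.

    d_ao: aortic root diameter (cm); height (cm); tac: total arterial
    compliance (mL/mmHg); tpr: total peripheral resistance (mmHg s/mL).
    """

    d_ao: float
    height: float
    tac: float
    tpr: float

    def __post_init__(self) -> None:
        for name in ("d_ao", "height", "tac", "tpr"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class VirtualSubject:
    """One virtual subject: cardiac + arterial parameters and a label."""

    cardiac: CardiacParams
    arterial: ArterialParams
    id: str = ""


@dataclass(frozen=True)
class SolverConfig:
    """Fixed-step implicit integrator settings."""

    dt: float = 5e-4            # s
    min_cycles: int = 8
    max_cycles: int = 30
    conv_tol: float = 0.1       # mmHg, cycle-to-cycle aortic SBP change
    theta: float = 0.6          # implicitness of the theta-scheme (0.5..1)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 1e-3:
            raise InvalidParameterError("solver time step must be in (0, 1] ms")
        if self.min_cycles < 2 or self.max_cycles < self.min_cycles:
            raise InvalidParameterError("need max_cycles >= min_cycles >= 2")
        if not (0.5 <= self.theta <= 1.0):
            raise InvalidParameterError("theta must lie in [0.5, 1.0]")


@dataclass
class SimulationResult:
    """One converged cardiac cycle on a uniform grid (plus cycle history)."""

    t: np.ndarray                     # s, one cycle starting at activation onset
    p_lv: np.ndarray                  # mmHg
    v_lv: np.ndarray                  # mL
    p_site: dict[str, np.ndarray]     # mmHg, keys = measurement sites
    q_ao: np.ndarray                  # mL/s, aortic root (valve) flow
    converged: bool
    n_cycles_run: int
    sbp_history: np.ndarray           # per-cycle aortic SBP, mmHg
    subject_id: str = ""
    cf_path_length: float = 0.0       # m, height-scaled carotid-femoral path


# ---------------------------------------------------------------------------
# elastance
# ---------------------------------------------------------------------------

def normalized_activation(t_norm, t_max: float):
    """Raised-cosine activation: 0->1 over [0, t_max], 1->0 over the next
    t_max/2, zero for the rest of the cycle.  Accepts scalars or arrays."""
    if t_max <= 0:
        raise InvalidParameterError(f"t_max must be positive, got {t_max}")
    t = np.asarray(t_norm, dtype=float)
    rise = 0.5 * (1.0 - np.cos(np.pi * t / t_max))
    fall = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - t_max) / t_max))
    out = np.where(t <= t_max, rise, np.where(t <= 1.5 * t_max, fall, 0.0))
    out = np.where(t < 0, 0.0, out)
    return out if out.ndim else float(out)


def elastance_at(t_norm, cardiac: CardiacParams):
    """Instantaneous LV elastance E(t) = E_ed + (E_es - E_ed) * activation."""
    act = normalized_activation(t_norm, cardiac.t_max)
    return cardiac.e_ed + (cardiac.e_es - cardiac.e_ed) * act


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

@dataclass
class ArterialTree:
    """Assembled RLC network for one subject.

    Nodes carry pressures (shunt compliance), elements carry flows (series
    R, L).  ``node_in``/``node_out`` index the element endpoints; terminal
    Windkessels attach at ``wk_node`` with series impedance ``wk_zc``,
    peripheral resistance ``wk_rp`` and compliance ``wk_cp``.
    """

    n_nodes: int
    node_c: np.ndarray            # mL/mmHg per node
    node_tau: np.ndarray          # s, effective Voigt wall time constant
    node_in: np.ndarray           # element inlet node index
    node_out: np.ndarray          # element outlet node index
    elem_l: np.ndarray            # mmHg s^2/mL
    elem_r: np.ndarray            # mmHg s/mL
    wk_node: np.ndarray           # node index per terminal
    wk_zc: np.ndarray             # mmHg s/mL
    wk_rp: np.ndarray             # mmHg s/mL
    wk_cp: np.ndarray             # mL/mmHg
    site_node: dict[str, int]
    cf_path_length: float         # m
    segments: list[dict]          # per-segment audit table
    tac: float
    tpr: float

    def total_compliance(self) -> float:
        """Sum of node and Windkessel compliances (equals the effective
        total compliance; identical to TAC at the population mean)."""
        return float(self.node_c.sum() + self.wk_cp.sum())

    def input_resistance(self) -> float:
        """DC resistance from the root node to the venous ground."""
        # series element resistances + terminal (Zc + Rp), reduced leaf-up
        node_r_down: dict[int, list[float]] = {}
        for k in range(len(self.wk_node)):
            node_r_down.setdefault(int(self.wk_node[k]), []).append(
                float(self.wk_zc[k] + self.wk_rp[k])
            )
        order = np.argsort(-self.node_out)  # children have larger indices
        for j in order:
            branches = node_r_down.pop(int(self.node_out[j]), [])
            g = sum(1.0 / r for r in branches)
            r_here = float(self.elem_r[j]) + (1.0 / g if g else np.inf)
            node_r_down.setdefault(int(self.node_in[j]), []).append(r_here)
        g = sum(1.0 / r for r in node_r_down.get(0, []))
        return 1.0 / g


def _tree_quantities(arterial: ArterialParams):
    """Per-element geometry, raw PWV-law compliance weights, resistances.

    Diameters taper linearly element-by-element from the segment's inlet
    ratio to its outlet ratio (a stepwise-constant profile would put a
    spurious impedance jump, hence a reflected wavelet, at every segment
    junction).  Only the aortic trunk follows the sampled root diameter;
    branch vessels keep reference calibre (arm size is not a cardiac
    trait).
    """
    scale = arterial.height / tpl.REF_HEIGHT
    # the reduced trunk's effective calibre varies sub-linearly with the
    # sampled root diameter (it stands for a whole averaged tree)
    d_eff = tpl.REF_DIAMETER * (arterial.d_ao / tpl.REF_DIAMETER) ** tpl.ROOT_DIAMETER_EXP
    segs = []
    for spec in tpl.SEGMENTS:
        d_base = d_eff if spec.scales_with_root else tpl.REF_DIAMETER
        r_start = (spec.diam_ratio_start if spec.diam_ratio_start is not None
                   else spec.diam_ratio)
        n_el = max(tpl.MIN_ELEMENTS,
                   int(np.ceil(spec.length / tpl.ELEMENT_LENGTH)))
        length = spec.length * scale
        l_el = length / n_el
        mids = (np.arange(n_el) + 0.5) / n_el
        d_el = (r_start + (spec.diam_ratio - r_start) * mids) * d_base
        area_el = np.pi * d_el ** 2 / 4.0
        pwv_el = tpl.PWV_COEFF * d_el ** (-tpl.PWV_EXPONENT)   # m/s, raw law
        # Bramwell-Hill: C' = A/(rho PWV^2); compliance_boost re-weights
        # limb segments so their calibrated wave speed stays physiologic
        # after the global rescale.
        c_el = (tpl.MMHG_CGS * area_el * l_el
                / (tpl.RHO * (pwv_el * 100.0) ** 2)) * spec.compliance_boost
        r_el = 8.0 * tpl.MU * l_el / (np.pi * (d_el / 2.0) ** 4) / tpl.MMHG_CGS
        li_el = tpl.RHO * l_el / (area_el * tpl.MMHG_CGS)
        segs.append(
            dict(spec=spec, n_elements=n_el, length=length,
                 diameter=float(d_el.mean()), d_el=d_el, area_el=area_el,
                 pwv_raw=float(pwv_el.mean()), pwv_el=pwv_el,
                 c_raw=float(c_el.sum()), c_el=c_el,
                 r=float(r_el.sum()), r_el=r_el,
                 l=float(li_el.sum()), l_el=li_el)
        )
    return segs


def _raw_compliance_sum(d_ao: float, height: float) -> float:
    params = ArterialParams(d_ao=d_ao, height=height, tac=1.0, tpr=1.0)
    return sum(s["c_raw"] for s in _tree_quantities(params))


def effective_compliance(tac: float) -> float:
    """Realized total compliance for a sampled TAC (identity at the mean).

    Emulates the reference model's pressure-dependent walls, whose realized
    stiffness range is much narrower than the sampled compliance range.
    """
    return tpl.REF_TAC * (tac / tpl.REF_TAC) ** tpl.TAC_EFFECTIVE_EXP


def tree_compliance_target(tac: float, d_ao: float = 3.0,
                           height: float = 175.0) -> float:
    """Compliance held by the tree itself (rest goes to the Windkessels).

    Proportional to the effective total compliance and to the raw
    diameter-law geometry; capped so the terminal share stays positive.
    """
    c_eff = effective_compliance(tac)
    geom = _raw_compliance_sum(d_ao, height) / _raw_compliance_sum(3.0, 175.0)
    c = (tpl.TREE_COMPLIANCE_REF * geom ** tpl.TREE_GEOMETRY_EXP
         * (c_eff / tpl.REF_TAC) ** tpl.TREE_COMPLIANCE_EXP)
    return min(c, tpl.TREE_COMPLIANCE_CAP * c_eff)


def build_arterial_tree(arterial: ArterialParams) -> ArterialTree:
    """Instantiate the template for one subject and calibrate totals.

    Segment compliances follow the inverse-power PWV law (relative profile)
    and are rescaled by one global factor so that tree + terminal
    compliance equals TAC exactly; terminal resistances are scaled so the
    root-to-ground DC resistance equals TPR.
    """
    if arterial.tac <= 0 or arterial.tpr <= 0:
        raise InvalidParameterError("TAC and TPR must be positive")
    segs = _tree_quantities(arterial)

    c_eff = effective_compliance(arterial.tac)
    c_tree = tree_compliance_target(arterial.tac, arterial.d_ao, arterial.height)
    c_scale = c_tree / sum(s["c_raw"] for s in segs)

    # --- assemble nodes/elements -----------------------------------------
    node_c: list[float] = [0.0]          # node 0 = aortic root
    node_tc: list[float] = [0.0]         # tau-weighted compliance per node
    node_in: list[int] = []
    node_out: list[int] = []
    elem_l: list[float] = []
    elem_r: list[float] = []
    seg_nodes: dict[str, list[int]] = {}  # inlet + per-element outlet nodes
    for s in segs:
        spec = s["spec"]
        # element count comes from the reference length so every subject
        # shares one state layout (element size, not count, absorbs height)
        n_el = s["n_elements"]
        if spec.parent is None:
            inlet = 0
        else:
            inlet = seg_nodes[spec.parent][-1]
        nodes = [inlet]
        tau = spec.visc_tau if spec.visc_tau is not None else tpl.WALL_VISC_TAU
        for e in range(n_el):
            c_el = s["c_el"][e] * c_scale
            node_c.append(0.0)
            node_tc.append(0.0)
            j = len(node_c) - 1
            node_in.append(nodes[-1])
            node_out.append(j)
            elem_l.append(s["l_el"][e])
            elem_r.append(s["r_el"][e])
            node_c[nodes[-1]] += 0.5 * c_el
            node_c[j] += 0.5 * c_el
            node_tc[nodes[-1]] += 0.5 * c_el * tau
            node_tc[j] += 0.5 * c_el * tau
            nodes.append(j)
        seg_nodes[spec.name] = nodes

    # --- terminal Windkessels ---------------------------------------------
    leaves = [s for s in segs if s["spec"].terminal_frac is not None]
    frac = np.array([s["spec"].terminal_frac for s in leaves])
    frac = frac / frac.sum()
    wk_node = np.array([seg_nodes[s["spec"].name][-1] for s in leaves])

    tree = ArterialTree(
        n_nodes=len(node_c),
        node_c=np.asarray(node_c),
        node_tau=np.asarray(node_tc) / np.asarray(node_c),
        node_in=np.asarray(node_in),
        node_out=np.asarray(node_out),
        elem_l=np.asarray(elem_l),
        elem_r=np.asarray(elem_r),
        wk_node=wk_node,
        wk_zc=np.zeros(len(leaves)),
        wk_rp=np.ones(len(leaves)),
        wk_cp=np.zeros(len(leaves)),
        site_node={},
        cf_path_length=tpl.cf_path_length(arterial.height),
        segments=[],
        tac=arterial.tac,
        tpr=arterial.tpr,
    )

    # terminal resistances: R_k = scale/frac_k split into Zc + Rp with Zc
    # matched to the feeding segment's characteristic impedance; solve the
    # scalar scale so the network DC input resistance equals TPR exactly.
    z0_feed = np.array([
        np.sqrt(s["l_el"][-1] / (s["c_el"][-1] * c_scale)) for s in leaves
    ])
    matched = np.array([s["spec"].zc_matched for s in leaves])

    def set_scale(s: float) -> None:
        r_tot = s / frac
        zc_m = np.minimum(z0_feed, tpl.TERMINAL_ZC_RCAP * r_tot)
        zc = np.where(matched, zc_m, tpl.TERMINAL_ZC_FRAC * r_tot)
        tree.wk_zc = zc
        tree.wk_rp = r_tot - zc

    from scipy.optimize import brentq

    def f(s: float) -> float:
        set_scale(s)
        return tree.input_resistance() - arterial.tpr

    hi = arterial.tpr * 2.0
    while f(hi) < 0:
        hi *= 2.0
    lo = arterial.tpr * 1e-3
    while f(lo) > 0:
        lo *= 0.5
    s_star = brentq(f, lo, hi, xtol=arterial.tpr * tpl.TERMINAL_R_TOL)
    set_scale(s_star)

    # terminal compliances: remainder of TAC, split by the template's
    # compliance shares (central beds hold most of it; the narrow measured
    # limbs end in nearly resistive loads, as at the arteriolar level)
    c_frac = np.array([s["spec"].compliance_frac for s in leaves])
    c_frac = c_frac / c_frac.sum()
    c_wk_total = c_eff - c_tree
    tree.wk_cp = c_wk_total * c_frac

    # --- sites and audit table --------------------------------------------
    for site, (seg_name, pos) in tpl.MEASUREMENT_SITES.items():
        nodes = seg_nodes[seg_name]
        idx = int(round(pos * (len(nodes) - 1)))
        tree.site_node[site] = nodes[idx]
    rho_mmhg = tpl.RHO / tpl.MMHG_CGS
    for s in segs:
        c_seg = s["c_raw"] * c_scale
        area_mean = float(s["area_el"].mean())
        pwv_eff = np.sqrt(area_mean * s["length"] / (rho_mmhg * c_seg)) / 100.0
        tree.segments.append(
            dict(name=s["spec"].name, parent=s["spec"].parent,
                 length=s["length"], diameter=s["diameter"],
                 n_elements=s["n_elements"], pwv_raw=s["pwv_raw"],
                 pwv_eff=pwv_eff, compliance=c_seg, resistance=s["r"],
                 inertance=s["l"],
                 terminal_frac=s["spec"].terminal_frac)
        )
    return tree


# ---------------------------------------------------------------------------
# linear-system assembly
# ---------------------------------------------------------------------------

def _assemble(tree: ArterialTree):
    """Linear system for one tree with Voigt viscoelastic walls.

    State layout x = [wall-capacitor pressures Pc (n), element flows Q (m),
    Windkessel pressures Pwk (k)]:

        dx/dt = A x + b Q_av + c_base P_ven
        P_node = W x + w_av Q_av        (algebraic node pressures)

    Each wall compliance C_i carries a series resistance R_w = tau_w / C_i,
    so the node pressure is the capacitor pressure plus the viscous term
    R_w * (net inflow); terminal branch flows are eliminated locally.
    """
    n, m, k = tree.n_nodes, len(tree.elem_l), len(tree.wk_node)
    dim = n + m + k
    rw = tree.node_tau / tree.node_c

    # net elemental inflow per node: S = S_mat x + s_av Q_av
    S_mat = np.zeros((n, dim))
    for j in range(m):
        S_mat[int(tree.node_in[j]), n + j] -= 1.0
        S_mat[int(tree.node_out[j]), n + j] += 1.0
    s_av = np.zeros(n)
    s_av[0] = 1.0

    # terminal flows: Q_t = Zd (Pc_t + rw_t S_t - Pwk)
    t_nodes = tree.wk_node.astype(int)
    rw_t = rw[t_nodes]
    zden = 1.0 / (tree.wk_zc + rw_t)
    Qt_mat = np.zeros((k, dim))
    Qt_mat[np.arange(k), t_nodes] = zden                     # Pc term
    Qt_mat += (zden * rw_t)[:, None] * S_mat[t_nodes]        # viscous term
    Qt_mat[np.arange(k), n + m + np.arange(k)] -= zden       # Pwk term
    qt_av = zden * rw_t * s_av[t_nodes]

    # node pressures: P = Pc + rw*(S - T Qt)
    W = np.zeros((n, dim))
    W[:, :n] = np.eye(n)
    W += rw[:, None] * S_mat
    W[t_nodes] -= (rw_t * 1.0)[:, None] * Qt_mat
    w_av = rw * s_av
    w_av[t_nodes] -= rw_t * qt_av

    A = np.zeros((dim, dim))
    b = np.zeros(dim)
    c_base = np.zeros(dim)
    # wall capacitors: dPc/dt = (S - T Qt)/C
    net = S_mat.copy()
    net[t_nodes] -= Qt_mat
    net_av = s_av.copy()
    net_av[t_nodes] -= qt_av
    A[:n] = net / tree.node_c[:, None]
    b[:n] = net_av / tree.node_c
    # element flows: dQ/dt = (P_in - P_out - R Q)/L
    Bt = np.zeros((m, n))
    for j in range(m):
        Bt[j, int(tree.node_in[j])] = 1.0
        Bt[j, int(tree.node_out[j])] = -1.0
    A[n:n + m] = (Bt @ W) / tree.elem_l[:, None]
    A[n + np.arange(m), n + np.arange(m)] -= tree.elem_r / tree.elem_l
    b[n:n + m] = (Bt @ w_av) / tree.elem_l
    # Windkessels: dPwk/dt = (Qt - (Pwk - Pven)/Rp)/Cw
    A[n + m:] = Qt_mat / tree.wk_cp[:, None]
    A[n + m + np.arange(k), n + m + np.arange(k)] -= 1.0 / (tree.wk_rp * tree.wk_cp)
    b[n + m:] = qt_av / tree.wk_cp
    c_base[n + m:] = 1.0 / (tree.wk_rp * tree.wk_cp)
    return A, b, c_base, W, w_av, dim


# ---------------------------------------------------------------------------
# batched implicit integrator
# ---------------------------------------------------------------------------

class _BatchSystem:
    """Precomputed implicit-step operators for a batch of subjects."""

    def __init__(self, subjects: list[VirtualSubject], solver: SolverConfig):
        self.subjects = subjects
        self.solver = solver
        self.trees = [build_arterial_tree(s.arterial) for s in subjects]
        dims = {t.n_nodes + len(t.elem_l) + len(t.wk_node) for t in self.trees}
        if len(dims) != 1:
            raise SimulationFailureError("template produced ragged state dims")
        self.dim = dims.pop()
        B = len(subjects)
        dt = solver.dt
        th = solver.theta
        site_order = ("aortic_root", "brachial", "carotid", "femoral")
        self.site_order = site_order
        self.prop = np.empty((B, self.dim, self.dim))
        self.g = np.empty((B, self.dim))
        self.h = np.empty((B, self.dim))
        self.w_site = np.empty((B, len(site_order), self.dim))
        self.wav_site = np.empty((B, len(site_order)))
        eye = np.eye(self.dim)
        for i, tree in enumerate(self.trees):
            A, b, c_base, W, w_av, _ = _assemble(tree)
            minv = np.linalg.inv(eye - th * dt * A)
            self.prop[i] = minv @ (eye + (1.0 - th) * dt * A)
            self.g[i] = dt * (minv @ b)
            self.h[i] = dt * (minv @ c_base) * tpl.P_VENOUS
            for j, site in enumerate(site_order):
                nd = tree.site_node[site]
                self.w_site[i, j] = W[nd]
                self.wav_site[i, j] = w_av[nd]
        # root-pressure Schur row: P_root = p0 + k Q_av at the new time level
        self.k_root = (
            th * np.einsum("bd,bd->b", self.w_site[:, 0], self.g)
            + self.wav_site[:, 0]
        )
        card = [s.cardiac for s in subjects]
        self.e_es = np.array([c.e_es for c in card])
        # sub-linear effective diastolic stiffness (exponential-EDPVR
        # emulation; identity at the population-mean E_ed)
        self.e_ed = np.array([
            tpl.REF_EED * (c.e_ed / tpl.REF_EED) ** tpl.EED_EFFECTIVE_EXP
            for c in card
        ])
        self.v_d = np.array([c.v_d for c in card])
        self.t_max = np.array([c.t_max for c in card])
        self.p_fill = np.array([c.p_fill for c in card])
        self.period = np.array([c.period for c in card])
        self.r_av = tpl.R_AORTIC_VALVE
        self.r_mv = tpl.R_MITRAL_VALVE

    # -- initial state ------------------------------------------------------
    def initial_state(self):
        """Start near the expected operating point to shorten settling."""
        B = len(self.subjects)
        x = np.zeros((B, self.dim))
        v = np.empty(B)
        for i, s in enumerate(self.subjects):
            c, a = s.cardiac, s.arterial
            e_ed = float(self.e_ed[i])
            pmap = 90.0
            for _ in range(4):
                esv = c.v_d + 1.0 * pmap / c.e_es
                veq = c.v_d + c.p_fill / e_ed
                t_fill = max(0.1, c.period - 1.2 * c.t_max)
                edv = veq - (veq - esv) * np.exp(-t_fill * e_ed / self.r_mv)
                sv = max(edv - esv, 5.0)
                pmap = float(np.clip(sv / c.period * a.tpr + c.p_fill,
                                     40.0, 160.0))
            x[i, : self.trees[i].n_nodes] = pmap
            x[i, self.trees[i].n_nodes + len(self.trees[i].elem_l):] = pmap
            v[i] = edv
        return x, v

    # -- one implicit step --------------------------------------------------
    def step(self, x, v, t, q_av_prev):
        """Advance the batch from t to t+dt; returns (x, v, q_av, p_lv, p_root)."""
        dt = self.solver.dt
        th = self.solver.theta
        u = np.matmul(self.prop, x[:, :, None])[:, :, 0] \
            + (1.0 - th) * self.g * q_av_prev[:, None] + self.h
        p0 = np.einsum("bd,bd->b", self.w_site[:, 0], u)
        tn = np.mod(t + dt, self.period)
        act = _activation_vec(tn, self.t_max)
        E = self.e_ed + (self.e_es - self.e_ed) * act
        a = E * dt
        pv = E * (v - self.v_d)
        k = self.k_root
        r_av, r_mv = self.r_av, self.r_mv

        # candidate valve configurations (vectorised closed forms)
        q_av_only = (pv - p0) / (r_av + a + k)
        q_mv_only = (self.p_fill - pv) / (r_mv + a)
        a11 = r_av + a + k
        a12 = -a
        a21 = a
        a22 = -(r_mv + a)
        det = a11 * a22 - a12 * a21
        rhs1 = pv - p0
        rhs2 = pv - self.p_fill
        q_av_b = (rhs1 * a22 - a12 * rhs2) / det
        q_mv_b = (a11 * rhs2 - a21 * rhs1) / det

        both_ok = (q_av_b > 0) & (q_mv_b > 0)
        av_ok = (~both_ok) & (q_av_only > 0) & \
            (self.p_fill <= pv + a * (-q_av_only))
        mv_ok = (~both_ok) & (~av_ok) & (q_mv_only > 0) & \
            (pv + a * q_mv_only <= p0)
        q_av = np.where(both_ok, q_av_b, np.where(av_ok, q_av_only, 0.0))
        q_mv = np.where(both_ok, q_mv_b, np.where(mv_ok, q_mv_only, 0.0))

        v_new = v + dt * (q_mv - q_av)
        x_new = u + th * self.g * q_av[:, None]
        p_lv = E * (v_new - self.v_d)
        p_root = p0 + self.k_root * q_av
        return x_new, v_new, q_av, p_lv, p_root

    def site_pressures(self, x, q_av):
        """Node pressures at the four measurement sites (B, 4)."""
        return (np.matmul(self.w_site, x[:, :, None])[:, :, 0]
                + self.wav_site * q_av[:, None])


def _activation_vec(tn, t_max):
    rise = 0.5 * (1.0 - np.cos(np.pi * tn / t_max))
    fall = 0.5 * (1.0 + np.cos(2.0 * np.pi * (tn - t_max) / t_max))
    return np.where(tn <= t_max, rise, np.where(tn <= 1.5 * t_max, fall, 0.0))


def _simulate_batch(subjects: list[VirtualSubject],
                    solver: SolverConfig) -> list[SimulationResult]:
    sysb = _BatchSystem(subjects, solver)
    B = len(subjects)
    dt = solver.dt
    x, v = sysb.initial_state()
    q_av = np.zeros(B)
    t = 0.0

    # per-cycle aortic SBP tracking (generous cap: HR spread means fast
    # subjects run more cycles than max_cycles before the slowest finishes)
    max_hist = 2 * solver.max_cycles + 8
    sbp_hist = np.full((B, max_hist), np.nan)
    cyc_idx = np.zeros(B, dtype=int)
    cur_max = np.full(B, -np.inf)

    def track(p_root, t_next):
        nonlocal cur_max
        new_cyc = np.floor(t_next / sysb.period + 1e-12).astype(int)
        rolled = new_cyc > cyc_idx
        if np.any(rolled):
            idx = np.clip(cyc_idx[rolled], 0, max_hist - 1)
            sbp_hist[rolled, idx] = cur_max[rolled]
            cyc_idx[rolled] = new_cyc[rolled]
            cur_max[rolled] = -np.inf
        cur_max = np.maximum(cur_max, p_root)

    t_max_period = float(sysb.period.max())

    def converged_mask():
        ok = np.zeros(B, dtype=bool)
        for i in range(B):
            n = min(int(cyc_idx[i]), max_hist - 1)
            if cyc_idx[i] >= solver.min_cycles:
                d = abs(sbp_hist[i, n - 1] - sbp_hist[i, n - 2])
                ok[i] = np.isfinite(d) and d < solver.conv_tol
        return ok

    # settle phase: chunks of ~2 longest cycles, stop when all converged
    while True:
        n_chunk = int(np.ceil(2.0 * t_max_period / dt))
        for _ in range(n_chunk):
            x, v, q_av, p_lv, p_root = sysb.step(x, v, t, q_av)
            t += dt
            track(p_root, t)
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(v)):
            raise SimulationFailureError("non-finite state during settling")
        if np.all(converged_mask()):
            break
        if int(cyc_idx.min()) >= solver.max_cycles - 2:
            break

    # recording phase: two more cycles of the slowest subject
    n_rec = int(np.ceil(2.0 * t_max_period / dt)) + 2
    rec_t = np.empty(n_rec)
    rec = {name: np.empty((B, n_rec)) for name in
           ("p_root", "p_brachial", "p_carotid", "p_femoral", "v_lv",
            "q_ao", "p_lv")}
    for j in range(n_rec):
        x, v, q_av, p_lv, p_root = sysb.step(x, v, t, q_av)
        t += dt
        track(p_root, t)
        rec_t[j] = t
        p_sites = sysb.site_pressures(x, q_av)
        rec["p_root"][:, j] = p_sites[:, 0]
        rec["p_brachial"][:, j] = p_sites[:, 1]
        rec["p_carotid"][:, j] = p_sites[:, 2]
        rec["p_femoral"][:, j] = p_sites[:, 3]
        rec["v_lv"][:, j] = v
        rec["q_ao"][:, j] = q_av
        rec["p_lv"][:, j] = p_lv
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(v)):
        raise SimulationFailureError("non-finite state during recording")

    # slice the last complete cycle of each subject
    results: list[SimulationResult] = []
    for i, subj in enumerate(subjects):
        T = sysb.period[i]
        k_end = int(np.floor(rec_t[-1] / T + 1e-12))
        t_lo, t_hi = (k_end - 1) * T, k_end * T
        j_lo = int(np.searchsorted(rec_t, t_lo - 1e-12))
        j_hi = int(np.searchsorted(rec_t, t_hi - 1e-12))
        sl = slice(j_lo, j_hi)
        n_cycles = int(cyc_idx[i])
        hist = sbp_hist[i, :min(n_cycles, max_hist)]
        hist = hist[np.isfinite(hist)]
        conv = (
            len(hist) >= 2
            and n_cycles >= solver.min_cycles
            and abs(hist[-1] - hist[-2]) < solver.conv_tol
        )
        results.append(SimulationResult(
            t=rec_t[sl] - rec_t[j_lo],
            p_lv=rec["p_lv"][i, sl].copy(),
            v_lv=rec["v_lv"][i, sl].copy(),
            p_site={
                "aortic_root": rec["p_root"][i, sl].copy(),
                "brachial": rec["p_brachial"][i, sl].copy(),
                "carotid": rec["p_carotid"][i, sl].copy(),
                "femoral": rec["p_femoral"][i, sl].copy(),
            },
            q_ao=rec["q_ao"][i, sl].copy(),
            converged=bool(conv),
            n_cycles_run=n_cycles,
            sbp_history=hist.copy(),
            subject_id=subj.id,
            cf_path_length=sysb.trees[i].cf_path_length,
        ))
    return results


def simulate_beat(subject: VirtualSubject,
                  solver: SolverConfig | None = None) -> SimulationResult:
    """Integrate one subject to periodic steady state; see module docstring."""
    solver = solver or SolverConfig()
    return _simulate_batch([subject], solver)[0]


def simulate_population(subjects: list[VirtualSubject],
                        solver: SolverConfig | None = None,
                        batch_size: int = 128,
                        progress: bool = False) -> list[SimulationResult]:
    """Simulate many subjects in fixed-size batches (order preserved)."""
    solver = solver or SolverConfig()
    out: list[SimulationResult] = []
    for lo in range(0, len(subjects), batch_size):
        out.extend(_simulate_batch(subjects[lo:lo + batch_size], solver))
        if progress:
            print(f"  simulated {min(lo + batch_size, len(subjects))}"
                  f"/{len(subjects)} subjects", flush=True)
    return out


def waveforms_to_frame(result: SimulationResult):
    """One converged cycle as a tidy table (subject_id, site, t, value)."""
    import pandas as pd

    frames = []
    sites = dict(result.p_site)
    sites["lv_pressure"] = result.p_lv
    sites["lv_volume"] = result.v_lv
    sites["aortic_flow"] = result.q_ao
    for site, values in sites.items():
        frames.append(pd.DataFrame({
            "subject_id": result.subject_id,
            "site": site,
            "t": result.t,
            "value": values,
        }))
    return pd.concat(frames, ignore_index=True)


def steady_state_error(result: SimulationResult) -> float:
    """Cycle-to-cycle aortic SBP difference (mmHg) of the last two cycles."""
    if len(result.sbp_history) < 2:
        raise PreconditionError("need at least two simulated cycles")
    return float(abs(result.sbp_history[-1] - result.sbp_history[-2]))
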