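"""Simulator unit and property tests: elastance waveform, tree calibration,
beat-level conservation laws, determinism, and paired monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import mean_subject
from hemopred import template as tpl
from hemopred.errors import InvalidParameterError, PreconditionError
from hemopred.simulator import (
    ArterialParams,
    ArterialTree,
    CardiacParams,
    SolverConfig,
    _assemble,
    _BatchSystem,
    build_arterial_tree,
    elastance_at,
    normalized_activation,
    simulate_beat,
    steady_state_error,
)


class TestActivation:
    def test_endpoint_values(self):
        assert normalized_activation(0.0, 0.34) == pytest.approx(0.0)
        assert normalized_activation(0.34, 0.34) == pytest.approx(1.0)
        # raised cosine at half the rise time: 0.5*(1 - cos(pi/2)) = 0.5
        assert normalized_activation(0.17, 0.34) == pytest.approx(0.5)
        assert normalized_activation(0.6, 0.34) == pytest.approx(0.0)

    def test_invalid_t_max(self):
        with pytest.raises(InvalidParameterError):
            normalized_activation(0.1, 0.0)

    @given(st.floats(0.0, 0.9))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_and_continuous(self, t):
        t_max = 0.34
        val = normalized_activation(t, t_max)
        assert 0.0 <= val <= 1.0
        nxt = normalized_activation(t + 1e-6, t_max)
        assert abs(nxt - val) < 1e-4  # continuity across the pieces


class TestElastance:
    def test_table_endpoints(self):
        card = CardiacParams(e_es=2.29, e_ed=0.12, p_fill=15.0, hr=75.0)
        assert elastance_at(0.0, card) == pytest.approx(0.12)
        assert elastance_at(card.t_max, card) == pytest.approx(2.29)

    def test_midpoint_mixture(self):
        card = CardiacParams(e_es=2.0, e_ed=0.1, p_fill=15.0, hr=75.0)
        assert elastance_at(card.t_max / 2, card) == pytest.approx(1.05)

    def test_invariant_validation(self):
        with pytest.raises(InvalidParameterError):
            CardiacParams(e_es=2.0, e_ed=2.4, p_fill=15.0, hr=75.0)
        with pytest.raises(InvalidParameterError):
            CardiacParams(e_es=2.0, e_ed=0.1, p_fill=15.0, hr=75.0, t_max=0.9)


class TestTreeCalibration:
    def test_total_compliance_equals_tac(self):
        tree = build_arterial_tree(
            ArterialParams(d_ao=3.0, height=175.0, tac=1.86, tpr=0.8)
        )
        assert tree.total_compliance() == pytest.approx(1.86, rel=1e-6)

    def test_input_resistance_equals_tpr(self):
        for tpr in (0.5, 0.8, 1.3):
            tree = build_arterial_tree(
                ArterialParams(d_ao=3.0, height=175.0, tac=1.86, tpr=tpr)
            )
            assert tree.input_resistance() == pytest.approx(tpr, rel=1e-3)

    def test_reference_height_keeps_template_lengths(self):
        tree = build_arterial_tree(
            ArterialParams(d_ao=3.0, height=175.0, tac=1.86, tpr=0.8)
        )
        by_name = {s["name"]: s["length"] for s in tree.segments}
        for spec in tpl.SEGMENTS:
            assert by_name[spec.name] == pytest.approx(spec.length)

    def test_height_scales_lengths_linearly(self):
        tall = build_arterial_tree(
            ArterialParams(d_ao=3.0, height=192.5, tac=1.86, tpr=0.8)
        )
        by_name = {s["name"]: s["length"] for s in tall.segments}
        for spec in tpl.SEGMENTS:
            assert by_name[spec.name] == pytest.approx(1.1 * spec.length)

    def test_smaller_diameter_raises_raw_local_pwv(self):
        # the inverse power law acts on the aortic trunk; branch vessels
        # keep reference calibre by design (see the tree template)
        small = build_arterial_tree(
            ArterialParams(d_ao=2.0, height=175.0, tac=1.86, tpr=0.8)
        )
        large = build_arterial_tree(
            ArterialParams(d_ao=3.0, height=175.0, tac=1.86, tpr=0.8)
        )
        trunk = {spec.name for spec in tpl.SEGMENTS if spec.scales_with_root}
        assert trunk
        for s, l in zip(small.segments, large.segments):
            if s["name"] in trunk:
                assert s["pwv_raw"] > l["pwv_raw"]
            else:
                assert s["pwv_raw"] == pytest.approx(l["pwv_raw"])

    def test_nonpositive_tac_rejected(self):
        with pytest.raises(InvalidParameterError):
            ArterialParams(d_ao=3.0, height=175.0, tac=-1.0, tpr=0.8)


class TestBeat:
    def test_mean_subject_asbp_in_population_range(self, mean_result):
        asbp = mean_result.p_site["aortic_root"].max()
        assert 76.05 <= asbp <= 188.31
        assert mean_result.converged

    def test_deterministic_repeat_is_bitwise_identical(self):
        a = simulate_beat(mean_subject())
        b = simulate_beat(mean_subject())
        assert np.array_equal(a.p_site["aortic_root"], b.p_site["aortic_root"])
        assert np.array_equal(a.v_lv, b.v_lv)
        assert np.array_equal(a.q_ao, b.q_ao)

    def test_volume_conservation(self, mean_result):
        r = mean_result
        sv = r.v_lv.max() - r.v_lv.min()
        ejected = np.trapezoid(r.q_ao, r.t)
        assert abs(ejected - sv) / sv < 0.01

    def test_flow_pressure_consistency(self, mean_result):
        # Windkessels drain to the filling pressure, so the perfusion
        # pressure MAP - P_fill must match CO * TPR
        r = mean_result
        sv = r.v_lv.max() - r.v_lv.min()
        hr = 82.57
        map_minus_ven = r.p_site["aortic_root"].mean() - 15.12
        assert map_minus_ven == pytest.approx(sv * hr / 60.0 * 0.80, rel=0.08)

    def test_min_volume_above_dead_volume(self, mean_result):
        assert mean_result.v_lv.min() > 15.0

    def test_converged_steady_state_error_below_tolerance(self, mean_result):
        assert steady_state_error(mean_result) < 0.1

    def test_steady_state_error_requires_two_cycles(self, mean_result):
        import dataclasses

        short = dataclasses.replace(mean_result,
                                    sbp_history=mean_result.sbp_history[:1])
        with pytest.raises(PreconditionError):
            steady_state_error(short)


class TestMonotonicity:
    """Paired simulations differing in exactly one parameter."""

    def test_higher_ees_raises_ef(self):
        efs = []
        for e_es in (1.5, 3.0):
            r = simulate_beat(mean_subject(e_es=e_es))
            efs.append((r.v_lv.max() - r.v_lv.min()) / r.v_lv.max())
        assert efs[1] > efs[0]

    def test_higher_tpr_raises_map(self):
        maps = [simulate_beat(mean_subject(tpr=t)).p_site["aortic_root"].mean()
                for t in (0.6, 1.1)]
        assert maps[1] > maps[0]

    def test_lower_tac_raises_cfpwv(self):
        from hemopred.measurements import compute_cfpwv

        pwvs = []
        for tac in (1.2, 2.8):
            r = simulate_beat(mean_subject(tac=tac))
            pwvs.append(compute_cfpwv(r.p_site["carotid"],
                                      r.p_site["femoral"], r.t,
                                      r.cf_path_length))
        assert pwvs[0] > pwvs[1]


class TestDiastolicDecayLimit:
    def test_single_rc_compartment_decays_with_rc_time_constant(self):
        """With the valve shut and the network reduced to one RC
        compartment, root pressure must decay as exp(-t / RC)."""
        R, C = 1.2, 1.5
        tree = ArterialTree(
            n_nodes=2,
            node_c=np.array([1e-6, C]),
            node_tau=np.array([0.0, 0.0]),
            node_in=np.array([0]),
            node_out=np.array([1]),
            elem_l=np.array([1e-6]),
            elem_r=np.array([1e-4]),
            wk_node=np.array([1]),
            wk_zc=np.array([1e-4]),
            wk_rp=np.array([R]),
            wk_cp=np.array([1e-6]),
            site_node={"aortic_root": 0, "brachial": 1, "carotid": 1,
                       "femoral": 1},
            cf_path_length=0.5,
            segments=[],
            tac=C,
            tpr=R,
        )
        A, b, c_base, W, w_av, dim = _assemble(tree)
        dt = 5e-4
        theta = 0.6
        minv = np.linalg.inv(np.eye(dim) - theta * dt * A)
        prop = minv @ (np.eye(dim) + (1 - theta) * dt * A)
        x = np.zeros(dim)
        x[:2] = 100.0
        n = int(2.0 / dt)
        trace = np.empty(n)
        for i in range(n):
            x = prop @ x
            trace[i] = W[0] @ x
        t = dt * (1 + np.arange(n))
        k, a = np.polyfit(t, np.log(trace), 1)
        fit = np.exp(a + k * t)
        rel_err = np.sqrt(np.mean((fit - trace) ** 2)) / trace.mean()
        assert rel_err < 0.02
        assert -1.0 / k == pytest.approx(R * C, rel=0.02)


class TestSolverConfig:
    def test_rejects_large_step_and_bad_cycles(self):
        with pytest.raises(InvalidParameterError):
            SolverConfig(dt=2e-3)
        with pytest.raises(InvalidParameterError):
            SolverConfig(min_cycles=1)
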