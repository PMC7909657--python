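"""Qu-Chung ventricular model: currents, gating, single-cell and sheet behavior."""

import numpy as np
import pytest

from ectopy.heterogeneity import nested_binary_masks
from ectopy.quchung import (
    GATES,
    QuChungParams,
    QuChungState,
    currents,
    gate_kinetics,
    resting_state,
    simulate_cell,
    simulate_sheet,
)

# steady states and time constants of the Luo-Rudy rate formulas, frozen from
# direct scalar evaluation of the published alpha/beta expressions
LR1_REFERENCE = {
    -80.0: {"m": (0.0035304588, 0.0086470649), "h": (0.95468423, 7.071735),
            "j": (0.96995703, 26.060037), "x": (0.0087933857, 250.48396),
            "d": (0.0043820944, 8.9876007)},
    -40.0: {"m": (0.59578255, 0.13312892), "h": (0.0, 1.9576343),
            "j": (0.0, 10.751694), "x": (0.23637952, 570.66784),
            "d": (0.16017912, 28.526465)},
    0.0: {"m": (0.99477064, 0.065367055), "h": (0.0, 0.17975814),
          "j": (0.0, 3.4692073), "x": (0.86522187, 498.88037),
          "d": (0.92547721, 22.549053)},
}


@pytest.fixture(scope="module")
def p_mono():
    return QuChungParams()


@pytest.fixture(scope="module")
def p_bi():
    return QuChungParams().bistable()


def make_state(V, p, cai=1e-4):
    kin = gate_kinetics(V, p)
    return QuChungState(V, *[float(kin[g][0]) for g in GATES], cai)


class TestCurrents:
    def test_ik1_vanishes_at_reversal(self, p_mono):
        st = make_state(p_mono.EK1, p_mono)
        assert currents(st, p_mono)["I_K1"] == pytest.approx(0.0, abs=1e-12)

    def test_sodium_reversal_potential(self, p_mono):
        # RT/F * ln(140/10) with RT/F about 26.71 mV
        assert p_mono.ENa == pytest.approx(70.4, abs=0.15)
        assert p_mono.RTF == pytest.approx(26.71, abs=0.01)

    def test_background_current_offset(self, p_mono):
        st = make_state(-59.87, p_mono)
        assert currents(st, p_mono)["I_b"] == pytest.approx(0.0, abs=1e-12)

    def test_nonphysical_calcium_rejected(self, p_mono):
        with pytest.raises(ValueError):
            QuChungState(-80.0, 0, 1, 1, 0, 1, 0, cai=-1e-5)


class TestGating:
    def test_lr1_rates_match_reference(self, p_mono):
        for V, ref in LR1_REFERENCE.items():
            kin = gate_kinetics(V, p_mono)
            for g, (yinf, tau) in ref.items():
                if g == "d":  # steady state replaced; only the time constant is LR1
                    assert float(kin[g][1]) == pytest.approx(tau, rel=1e-4)
                    continue
                assert float(kin[g][0]) == pytest.approx(yinf, abs=1e-5)
                assert float(kin[g][1]) == pytest.approx(tau, rel=1e-4)

    def test_d_gate_midpoint(self, p_mono):
        kin = gate_kinetics(-p_mono.V0, p_mono)
        assert float(kin["d"][0]) == pytest.approx(0.5)

    def test_f_gate_midpoint_shifts_with_delta(self):
        p = QuChungParams(delta=-15.0)
        kin = gate_kinetics(-(p.V0 + p.delta), p)  # V = -9.5 mV
        assert float(kin["f"][0]) == pytest.approx(0.5)

    def test_f_is_an_inactivation_gate(self, p_mono):
        f_lo = float(gate_kinetics(-60.0, p_mono)["f"][0])
        f_hi = float(gate_kinetics(0.0, p_mono)["f"][0])
        assert f_lo > 0.9 > 0.1 > f_hi

    def test_gamma_scales_tau_x_exactly(self):
        p1, p4 = QuChungParams(gamma=1.0), QuChungParams(gamma=4.0)
        for V in (-80.0, -40.0, 0.0, 20.0):
            t1 = float(gate_kinetics(V, p1)["x"][1])
            t4 = float(gate_kinetics(V, p4)["x"][1])
            assert t4 == pytest.approx(4.0 * t1, rel=1e-12)


class TestSingleCell:
    def test_resting_cell_does_not_drift(self, p_mono):
        tr = simulate_cell(p_mono, t_end=2000.0, stim_amplitude=0.0)
        assert np.abs(tr.V - tr.V[0]).max() < 1.0

    def test_gates_stay_bounded(self, p_bi):
        tr = simulate_cell(p_bi, t_end=4000.0)
        gates = tr.y[1:7]
        assert gates.min() >= -1e-9 and gates.max() <= 1 + 1e-9

    def test_calcium_relaxes_exponentially_without_ical(self, p_mono):
        """With I_CaL off, [Ca]i decays to 0.1 uM at rate 0.07/ms (closed form)."""
        import dataclasses
        p = dataclasses.replace(p_mono, g_CaL=0.0)
        y0 = make_state(-81.0, p, cai=1e-3)
        tr = simulate_cell(p, t_end=100.0, stim_amplitude=0.0, y0=y0, n_eval=201)
        cai = tr.y[7]
        expected = 1e-4 + (1e-3 - 1e-4) * np.exp(-0.07 * tr.t)
        assert np.allclose(cai, expected, rtol=1e-3, atol=1e-7)

    def test_apd_monotone_in_gamma(self):
        apds = []
        for g in (1, 2, 3):
            tr = simulate_cell(QuChungParams(gamma=g), t_end=6000.0)
            apds.append(tr.apd90 if tr.repolarized else np.inf)
        assert apds[0] <= apds[1] <= apds[2]
        assert np.isfinite(apds[0])

    def test_apd_monotone_in_delta_shift(self):
        apds = []
        for d in (0.0, -5.0, -10.0):
            tr = simulate_cell(QuChungParams(delta=d), t_end=6000.0)
            apds.append(tr.apd90 if tr.repolarized else np.inf)
        assert apds[0] <= apds[1] <= apds[2]


class TestSheet:
    def test_kernel_matches_adaptive_reference_per_cell_type(self, p_mono, p_bi):
        """A 1x1 uncoupled sheet reproduces the adaptive single-cell solution."""
        for ct, pref in ((0, p_mono), (1, p_bi)):
            mask = np.full((1, 1), bool(ct))
            res = simulate_sheet(mask, c=0.0, p_mono=p_mono, p_bi=p_bi, t_end=2500.0,
                                 snapshot_times=np.arange(250, 2501, 250.0))
            tr = simulate_cell(pref, t_end=2500.0)
            for t, v in res.snapshots:
                assert abs(v[0, 0] - np.interp(t, tr.t, tr.V)) < 1.0

    def test_step_halving_convergence(self, p_mono, p_bi):
        (mask,) = nested_binary_masks((4, 12), [0.3], seed=2)
        finals = []
        for dt in (0.02, 0.01):
            res = simulate_sheet(mask, c=0.15, p_mono=p_mono, p_bi=p_bi,
                                 t_end=800.0, dt=dt)
            finals.append(res.final_V)
        diff = np.abs(finals[0] - finals[1])
        # small timing shifts concentrate error on moving fronts; the bulk must agree
        assert np.median(diff) < 0.5
        assert (diff > 2.0).mean() < 0.02

    def test_all_monostable_wave_repolarizes(self, p_mono, p_bi):
        mask = np.zeros((6, 30), dtype=bool)
        res = simulate_sheet(mask, c=0.15, p_mono=p_mono, p_bi=p_bi, t_end=2500.0)
        assert res.depolarized_counts.max() > 0.2 * mask.size  # a band of the wave in flight
        assert res.outcome == "normal propagation"
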