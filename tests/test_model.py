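"""Model equations: auxiliary hormone maps and the 13-state derivative."""

import math

import numpy as np
import pytest

from cycleopt import CycleState, DoseSchedule, ParameterSet, auxiliary_hormones, rhs
from cycleopt.params import PARAM_ORDER, STATE_ORDER


@pytest.fixture(scope="module")
def params():
    return ParameterSet()


def test_auxiliary_baseline_offsets(params):
    """With all masses zero and no dose, hormones equal their offsets."""
    zero = CycleState(**{k: 0.0 for k in STATE_ORDER})
    e2, p4, inh = auxiliary_hormones(zero, (0.0, 0.0), params)
    assert e2 == pytest.approx(params.e0)
    assert p4 == pytest.approx(params.p0)
    assert inh == pytest.approx(params.h0)


def test_auxiliary_exogenous_linearity(params):
    """Doses enter linearly through b1/b2 (unit couplings by default)."""
    zero = CycleState(**{k: 0.0 for k in STATE_ORDER})
    e2, p4, inh = auxiliary_hormones(zero, (20.0, 1.4), params)
    assert e2 == pytest.approx(params.e0 + 20.0)
    assert p4 == pytest.approx(params.p0 + 1.4)
    assert inh == pytest.approx(params.h0)  # inhibin has no exogenous input

    p_half = params.replace(b1=0.5, b2=2.0)
    e2b, p4b, _ = auxiliary_hormones(zero, (20.0, 1.4), p_half)
    assert e2b == pytest.approx(params.e0 + 0.5 * 20.0)
    assert p4b == pytest.approx(params.p0 + 2.0 * 1.4)


def test_auxiliary_hand_computation(params):
    """Default initial state reproduces a hand evaluation of the three
    linear combinations."""
    s = CycleState()
    e2, p4, inh = auxiliary_hormones(s, (0.0, 0.0), params)
    assert e2 == pytest.approx(
        params.e0 + params.e1 * s.GrF + params.e2 * s.DomF + params.e3 * s.Lut4)
    assert p4 == pytest.approx(
        params.p0 + params.p1 * s.Lut3 + params.p2 * s.Lut4)
    assert inh == pytest.approx(
        params.h0 + params.h1 * s.DomF + params.h2 * s.Lut2 + params.h3 * s.Lut3)


def test_auxiliary_rejects_negative_state(params):
    bad = np.zeros(13)
    bad[5] = -1.0
    with pytest.raises(ValueError):
        auxiliary_hormones(bad, (0.0, 0.0), params)


def test_rhs_zero_sources_zero_state(params):
    """With all synthesis/recruitment sources off and zero state, nothing
    moves."""
    p = params.replace(V0_LH=1e-300, V1_LH=1e-300, V_FSH=1e-300,
                       b=0.0, c1=1e-300, e0=0.0, p0=0.0, h0=0.0)
    zero = np.zeros(13)
    dy = rhs(0.0, zero, 0.0, (0.0, 0.0), p)
    assert np.allclose(dy, 0.0, atol=1e-250)


def test_rhs_p4_inhibition_limits(params):
    """As P4 grows, FSH synthesis and follicular recruitment vanish."""
    p = params.replace(w=1.0, q=1.0)
    s = CycleState()
    big_dose = (0.0, 1e9)
    dy = rhs(0.0, s, 1.0, big_dose, p)
    # dRP_FSH: synthesis term ~ V_FSH * w / P4 -> 0; release grows with P4,
    # so the derivative is dominated by (negative) release
    assert dy[2] < 0
    # recruitment term (b + c1 RcF) FSH / (1 + P4/q) -> 0: dRcF is pure outflow
    lh = s.LH
    expected_outflow = -p.c2 * lh ** p.alpha * s.RcF
    assert dy[4] == pytest.approx(expected_outflow, rel=1e-4)


def test_rhs_mass_chain_conservation(params):
    """Summed ovarian derivatives equal recruitment inflow minus the final
    luteal outflow (the stage chain neither creates nor destroys mass)."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        y = rng.uniform(0.1, 30.0, size=13)
        dy = rhs(0.0, y, 1.3, (5.0, 0.5), params)
        e2, p4, _ = auxiliary_hormones(y, (5.0, 0.5), params)
        recruit = (params.b + params.c1 * y[4]) * y[3] / (1 + p4 / params.q)
        np.testing.assert_allclose(dy[4:].sum(),
                                   recruit - params.k4 * y[12], rtol=1e-10)


def test_rhs_rejects_nonfinite(params):
    y = np.full(13, 1.0)
    with pytest.raises(ValueError):
        rhs(0.0, y, float("nan"), (0.0, 0.0), params)
    y[0] = float("inf")
    with pytest.raises(ValueError):
        rhs(0.0, y, 1.0, (0.0, 0.0), params)


def test_rhs_matches_independent_symbolic_transcription(params):
    """Cross-check against a second, independent sympy transcription of the
    full system, to 10+ significant digits at random states."""
    sympy = pytest.importorskip("sympy")

    def sym_rhs(yv, inh_delay, e2exo, p4exo, p):
        y = {k: sympy.Float(v, 30) for k, v in zip(STATE_ORDER, yv)}
        c = {k: sympy.Float(getattr(p, k), 30) for k in PARAM_ORDER
             if math.isfinite(getattr(p, k))}
        c.setdefault("w", sympy.oo)
        c.setdefault("q", sympy.oo)
        E2 = c["e0"] + c["e1"]*y["GrF"] + c["e2"]*y["DomF"] \
            + c["e3"]*y["Lut4"] + c["b1"]*e2exo
        P4 = c["p0"] + c["p1"]*y["Lut3"] + c["p2"]*y["Lut4"] + c["b2"]*p4exo
        syn_lh = (c["V0_LH"] + c["V1_LH"]*E2**8/(c["Km_LH"]**8 + E2**8)) \
            / (1 + P4/c["Ki_LH_P"])
        rel_lh = c["k_LH"]*(1 + c["c_LH_P"]*P4)*y["RP_LH"]/(1 + c["c_LH_E"]*E2)
        syn_fsh = c["V_FSH"]/(1 + inh_delay/c["Ki_FSH_Inh"] + P4/c["w"])
        rel_fsh = c["k_FSH"]*(1 + c["c_FSH_P"]*P4)*y["RP_FSH"] \
            / (1 + c["c_FSH_E"]*E2)**2
        rec = (c["b"] + c["c1"]*y["RcF"])*y["FSH"]/(1 + P4/c["q"])
        o_rcf = c["c2"]*y["LH"]**c["alpha"]*y["RcF"]
        o_grf = c["c3"]*y["LH"]*y["GrF"]
        o_dom = c["c4"]*y["LH"]**c["gamma"]*y["DomF"]
        exprs = [
            syn_lh - rel_lh,
            rel_lh/c["v"] - c["alpha_LH"]*y["LH"],
            syn_fsh - rel_fsh,
            rel_fsh/c["v"] - c["alpha_FSH"]*y["FSH"],
            rec - o_rcf,
            o_rcf - o_grf,
            o_grf - o_dom,
            o_dom - c["d1"]*y["Sc1"],
            c["d1"]*y["Sc1"] - c["d2"]*y["Sc2"],
            c["d2"]*y["Sc2"] - c["k1"]*y["Lut1"],
            c["k1"]*y["Lut1"] - c["k2"]*y["Lut2"],
            c["k2"]*y["Lut2"] - c["k3"]*y["Lut3"],
            c["k3"]*y["Lut3"] - c["k4"]*y["Lut4"],
        ]
        return np.array([float(e) for e in exprs])

    rng = np.random.default_rng(11)
    for p in (params, params.replace(w=0.8, q=0.3, b1=0.7, b2=1.3)):
        for _ in range(3):
            y = rng.uniform(0.05, 50.0, size=13)
            inh_d = float(rng.uniform(0.5, 10.0))
            dose = (float(rng.uniform(0, 30)), float(rng.uniform(0, 3)))
            got = rhs(0.0, y, inh_d, dose, p)
            want = sym_rhs(y, inh_d, dose[0], dose[1], p)
            np.testing.assert_allclose(got, want, rtol=1e-10)


def test_unmodified_limit_removes_p4_terms(params):
    """w, q -> inf reproduces the predecessor model exactly: the modified
    rhs with finite w,q differs, the limit does not."""
    y = np.abs(np.random.default_rng(3).normal(5, 2, size=13))
    base = rhs(0.0, y, 2.0, (0.0, 1.0), params.without_p4_inhibition())
    modified = rhs(0.0, y, 2.0, (0.0, 1.0), params.replace(w=0.5, q=0.5))
    assert not np.allclose(base, modified)
    relaxed = rhs(0.0, y, 2.0, (0.0, 1.0), params.replace(w=1e12, q=1e12))
    np.testing.assert_allclose(relaxed, base, rtol=1e-9)


class TestDoseSchedule:
    def test_constant_and_zero(self):
        d = DoseSchedule.constant(e2exo=20.0, p4exo=1.4)
        assert d.at(3.7) == (20.0, 1.4)
        z = DoseSchedule.zero()
        assert z.at(10.0) == (0.0, 0.0)

    def test_nodes_interpolation_clipped_nonnegative(self):
        t = np.linspace(0, 28, 15)
        v = np.zeros(15)
        v[5] = 40.0  # single spike: interpolant must not undershoot below 0
        d = DoseSchedule.from_nodes(t, e2_values=v)
        tt = np.linspace(0, 28, 2001)
        e2, p4 = d.sample(tt)
        assert np.all(e2 >= 0)
        assert np.all(p4 == 0)
        assert d.at(t[5])[0] == pytest.approx(40.0)
        assert e2.max() <= 40.0 + 1e-9  # non-overshooting interpolant

    def test_nodes_hit_node_values(self):
        t = np.array([0.0, 7.0, 14.0, 21.0, 28.0])
        v = np.array([0.0, 10.0, 5.0, 2.0, 0.0])
        d = DoseSchedule.from_nodes(t, p4_values=v)
        for ti, vi in zip(t, v):
            assert d.at(ti)[1] == pytest.approx(vi)

    def test_negative_nodes_rejected(self):
        with pytest.raises(ValueError):
            DoseSchedule.from_nodes(np.array([0.0, 1.0]),
                                    e2_values=np.array([1.0, -2.0]))

    def test_from_file(self, tmp_path):
        cfg = tmp_path / "dose.yaml"
        cfg.write_text(
            "e2exo: 20.0\np4exo:\n  times: [0, 14, 28]\n  values: [0, 2, 0]\n")
        d = DoseSchedule.from_file(cfg)
        assert d.at(5.0)[0] == 20.0
        assert d.at(14.0)[1] == pytest.approx(2.0)
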