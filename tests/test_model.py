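"""Unit and property tests for the core model: right-hand sides,
effective exponents, closed-form steady states and stability reports."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import osteodyn as od
from osteodyn.model import EffectiveExponents, power_law_rates


def normal_params(g11=1.1):
    return od.RemodelingParams(
        alpha1=3.0, alpha2=4.0, beta1=0.2, beta2=0.02,
        g11=g11, g12=1.0, g21=-0.5, g22=0.0,
    )


TUMOR = od.TumorParams(gamma_T=0.005, L_T=100.0, r11=0.005, r22=0.2)


# ---------------------------------------------------------------------------
# parameter validation

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(alpha1=-1.0),
        dict(beta2=0.0),
        dict(g11=0.0),
        dict(g12=-0.1),
        dict(g21=0.5),
        dict(g22=-0.2),
    ],
)
def test_remodeling_params_sign_constraints(kwargs):
    base = dict(alpha1=3.0, alpha2=4.0, beta1=0.2, beta2=0.02,
                g11=1.1, g12=1.0, g21=-0.5, g22=0.0)
    base.update(kwargs)
    with pytest.raises(od.ParameterError):
        od.RemodelingParams(**base)


def test_tumor_params_require_nonnegative_weights():
    with pytest.raises(od.ParameterError):
        od.TumorParams(gamma_T=0.005, L_T=100.0, r11=-0.001)
    with pytest.raises(od.ParameterError):
        od.TumorParams(gamma_T=-0.005, L_T=100.0)


def test_treatment_overdose_rejected():
    p = normal_params()
    trt = od.TreatmentParams(v1=0.05, v2=0.008, t_start=600.0)
    with pytest.raises(od.ParameterError, match="beta2"):
        trt.validate_against(p)


# ---------------------------------------------------------------------------
# effective exponents

def test_effective_exponents_reduce_to_baseline_without_tumor():
    p = normal_params()
    e = od.effective_exponents(p, TUMOR, 0.0)
    assert (e.e11, e.e12, e.e21, e.e22) == (p.g11, p.g12, p.g21, p.g22)


def test_effective_exponents_at_capacity():
    p = normal_params(g11=1.1)
    e = od.effective_exponents(p, TUMOR, TUMOR.L_T)
    assert e.e11 == pytest.approx(1.1055, abs=1e-12)  # 1.1 * 1.005
    assert e.e22 == pytest.approx(-0.2, abs=1e-12)    # 0.0 - 0.2


def test_effective_exponents_domain():
    p = normal_params()
    with pytest.raises(od.DomainError):
        od.effective_exponents(p, TUMOR, -1.0)
    with pytest.raises(od.DomainError):
        od.effective_exponents(p, TUMOR, TUMOR.L_T + 1.0)


@given(
    T=st.floats(0.0, 100.0),
    dT=st.floats(0.0, 50.0),
    r=st.floats(0.001, 0.5),
)
@settings(derandomize=True, max_examples=60, deadline=None)
def test_effective_exponents_monotone_in_tumor_burden(T, dT, r):
    """With positive weights, the tumor raises e11, weakens both paracrine
    channels and lowers e22, monotonically in T."""
    assume(T + dT <= 100.0)
    p = normal_params()
    tp = od.TumorParams(gamma_T=0.005, L_T=100.0, r11=r, r12=r, r21=r, r22=r)
    a = od.effective_exponents(p, tp, T)
    b = od.effective_exponents(p, tp, T + dT)
    assert b.e11 >= a.e11
    assert b.e12 <= a.e12
    assert b.e21 <= a.e21  # more negative: stronger |e21|
    assert b.e22 <= a.e22


# ---------------------------------------------------------------------------
# right-hand sides

def test_rhs_normal_hand_computed_values():
    p = normal_params(g11=0.5)
    assert od.rhs_normal(1.0, 1.0, p) == pytest.approx((2.8, 3.98))
    assert od.rhs_normal(4.0, 1.0, p) == pytest.approx((5.2, 15.98))


def test_rhs_normal_vanishes_at_steady_state():
    p = normal_params(g11=0.5)
    Cbar, Bbar = od.steady_state(p)
    dC, dB = od.rhs_normal(Cbar, Bbar, p)
    assert abs(dC) < 1e-9 * p.beta1 * Cbar
    assert abs(dB) < 1e-9 * p.beta2 * Bbar


def test_rhs_normal_rejects_nonpositive_populations():
    p = normal_params()
    with pytest.raises(od.DomainError):
        od.rhs_normal(0.0, 1.0, p)
    with pytest.raises(od.DomainError):
        od.rhs_normal(1.0, -2.0, p)


def test_gompertz_rate_values():
    # at capacity the growth vanishes; at T=1 it is gamma*ln(L_T)
    assert od.rhs_tumor(1.0, 1.0, 100.0, normal_params(), TUMOR)[2] == 0.0
    dT = od.rhs_tumor(1.0, 1.0, 1.0, normal_params(), TUMOR)[2]
    assert dT == pytest.approx(0.005 * math.log(100.0), rel=1e-12)


def test_tumor_decoupling_with_zero_weights(rng):
    """With all r_ij = 0 the (C, B) rates are identical to the tumor-free
    model at machine precision."""
    p = normal_params()
    tp0 = od.TumorParams(gamma_T=0.005, L_T=100.0)
    C = rng.uniform(0.1, 30.0, size=1000)
    B = rng.uniform(1.0, 500.0, size=1000)
    T = rng.uniform(0.0, 100.0, size=1000)
    dC0, dB0 = od.rhs_normal(C, B, p)
    dC, dB, _ = od.rhs_tumor(C, B, T, p, tp0)
    np.testing.assert_array_equal(dC, dC0)
    np.testing.assert_array_equal(dB, dB0)


def test_rhs_treated_before_start_equals_untreated():
    p = normal_params()
    trt = od.TreatmentParams(v1=0.001, v2=0.008, t_start=600.0)
    a = od.rhs_treated(3.0, 250.0, 40.0, 100.0, p, TUMOR, trt)
    b = od.rhs_tumor(3.0, 250.0, 40.0, p, TUMOR)
    assert a == tuple(pytest.approx(x) for x in b)


def test_rhs_treated_null_treatment_is_identity():
    p = normal_params()
    trt = od.TreatmentParams(v1=0.0, v2=0.0, t_start=0.0)
    for t in (0.0, 500.0, 2000.0):
        a = od.rhs_treated(3.0, 250.0, 40.0, t, p, TUMOR, trt)
        b = od.rhs_tumor(3.0, 250.0, 40.0, p, TUMOR)
        assert np.allclose(a, b, rtol=0, atol=0)


def test_rhs_treated_tumor_decay_rate():
    """At half capacity under treatment the net Gompertz constant is
    gamma_T - v2 = -0.003, giving dT/dt = -0.003*50*ln 2."""
    p = normal_params()
    trt = od.TreatmentParams(v1=0.001, v2=0.008, t_start=600.0)
    dT = od.rhs_treated(3.0, 250.0, 50.0, 600.0, p, TUMOR, trt)[2]
    assert dT == pytest.approx(-0.003 * 50.0 * math.log(2.0), rel=1e-12)


# ---------------------------------------------------------------------------
# steady states

@pytest.mark.parametrize(
    "g11, expected",
    [(0.5, (1.06, 212.13)), (1.1, (1.16, 231.72))],
)
def test_normal_steady_state_matches_published(g11, expected):
    Cbar, Bbar = od.steady_state(normal_params(g11))
    assert round(Cbar, 2) == expected[0]
    assert round(Bbar, 2) == expected[1]


def test_trivial_steady_state_with_zero_exponents():
    p = od.RemodelingParams(
        alpha1=2.0, alpha2=3.0, beta1=2.0, beta2=3.0,
        g11=1.0, g12=1.0, g21=-1.0, g22=0.0,
    )
    e = EffectiveExponents(0.0, 0.0, 0.0, 0.0)
    assert od.steady_state(p, e) == (1.0, 1.0)


def test_degenerate_exponents_raise():
    p = normal_params()
    # e11 = 1 and e21 = 0 give gamma = e12*0 - 0*(1-e22) = 0
    e = EffectiveExponents(e11=1.0, e12=1.0, e21=0.0, e22=0.0)
    with pytest.raises(od.DegenerateParameterError):
        od.steady_state(p, e)


@given(
    a1=st.floats(0.1, 10.0), a2=st.floats(0.1, 10.0),
    b1=st.floats(0.01, 2.0), b2=st.floats(0.01, 2.0),
    g11=st.floats(0.1, 1.5), g12=st.floats(0.2, 1.5),
    g21=st.floats(-1.5, -0.2), g22=st.floats(0.0, 0.9),
)
@settings(derandomize=True, max_examples=80, deadline=None)
def test_steady_state_residual_property(a1, a2, b1, b2, g11, g12, g21, g22):
    """The closed form annihilates the right-hand side for arbitrary valid
    parameters (relative residual < 1e-9)."""
    p = od.RemodelingParams(a1, a2, b1, b2, g11, g12, g21, g22)
    gamma = g12 * g21 - (1 - g11) * (1 - g22)
    assume(abs(gamma) > 0.05)
    Cbar, Bbar = od.steady_state(p)
    assume(1e-6 < Cbar < 1e6 and 1e-6 < Bbar < 1e6)
    dC, dB = od.rhs_normal(Cbar, Bbar, p)
    scale = math.hypot(b1 * Cbar, b2 * Bbar)
    assert math.hypot(dC, dB) / scale < 1e-9


# ---------------------------------------------------------------------------
# Jacobian and stability

def test_jacobian_diagonal_reduces_at_steady_state():
    p = normal_params(g11=1.1)
    e = od.effective_exponents(p, TUMOR, TUMOR.L_T)
    Cbar, Bbar = od.steady_state(p, e)
    J = od.jacobian_at(p, Cbar, Bbar, e)
    assert J[0, 0] == pytest.approx(p.beta1 * (e.e11 - 1.0), rel=1e-9)
    assert J[1, 1] == pytest.approx(p.beta2 * (e.e22 - 1.0), rel=1e-9)


@pytest.mark.parametrize(
    "g11, expected_trace",
    [(1.1, 0.0), (0.5, -0.12)],
)
def test_jacobian_trace_values(g11, expected_trace):
    p = normal_params(g11)
    Cbar, Bbar = od.steady_state(p)
    J = od.jacobian_at(p, Cbar, Bbar)
    assert np.trace(J) == pytest.approx(expected_trace, abs=1e-12)


def test_stability_report_regimes_match_published_surface():
    p = normal_params(1.1)
    rep4 = od.stability_report(p, TUMOR)
    assert rep4.regime == "damped"
    assert round(rep4.max_re_eig, 5) == -0.00145
    tp6 = od.TumorParams(gamma_T=0.005, L_T=100.0, r11=0.02, r22=0.2)
    rep6 = od.stability_report(p, tp6)
    assert rep6.regime == "unstable"
    assert round(rep6.max_re_eig, 4) == 0.0002
    rep3 = od.stability_report(p)
    assert rep3.regime == "periodic"
    assert abs(rep3.max_re_eig) <= rep3.tolerance


def test_max_re_eig_agrees_with_numpy_eigenvalues():
    """Independent oracle: numpy's eigenvalue solver on the full Jacobian."""
    p = normal_params(1.1)
    for tp in (None, TUMOR):
        rep = od.stability_report(p, tp)
        e = rep.exponents
        J = od.jacobian_at(p, rep.Cbar, rep.Bbar, e)
        lam = np.linalg.eigvals(J)
        assert rep.max_re_eig == pytest.approx(lam.real.max(), abs=1e-14)


def test_complex_pair_real_part_is_half_trace():
    p = normal_params(1.1)
    rep = od.stability_report(p, TUMOR)
    J = od.jacobian_at(p, rep.Cbar, rep.Bbar, rep.exponents)
    trace = J[0, 0] + J[1, 1]
    disc = trace**2 - 4 * np.linalg.det(J)
    assert disc < 0  # complex-conjugate pair
    assert abs(rep.max_re_eig - trace / 2.0) <= 1e-12
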