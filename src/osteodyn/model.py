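"""Core model definitions: parameter types, right-hand sides, steady states,
and Jacobian-based stability classification.

The model describes the coupled dynamics of osteoclasts (bone-resorbing
cells, density ``C``) and osteoblasts (bone-forming cells, density ``B``)
in a basic multicellular unit.  Cell production is governed by power-law
autocrine/paracrine interactions::

    dC/dt = alpha1 * C**g11 * B**g21 - beta1 * C
    dB/dt = alpha2 * C**g12 * B**g22 - beta2 * B

with ``g11 > 0`` (osteoclast autocrine promotion), ``g21 < 0`` (osteoblast-
derived inhibition of osteoclasts), ``g12 > 0`` (osteoclast-derived promotion
of osteoblasts) and ``g22 >= 0`` (osteoblast autocrine signaling).

A myeloma tumor of density ``T`` growing by Gompertz kinetics,
``dT/dt = gamma_T * T * log(L_T / T)``, dysregulates the signaling by
perturbing the four exponents in proportion to the tumor burden ``T/L_T``.
Proteasome-inhibitor-style treatment is modeled as step forcing that lowers
the osteoblast removal rate (promoting osteoblast accumulation) and lowers
the tumor growth constant (extinguishing the tumor when the intensity
exceeds ``gamma_T``).

All quantities are dimensionless; time is measured in days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "ParameterError",
    "DomainError",
    "DegenerateParameterError",
    "RemodelingParams",
    "TumorParams",
    "TreatmentParams",
    "BoneMassParams",
    "State0D",
    "EffectiveExponents",
    "StabilityReport",
    "effective_exponents",
    "rhs_normal",
    "rhs_tumor",
    "rhs_treated",
    "steady_state",
    "jacobian_at",
    "stability_report",
    "gompertz_rate",
    "power_law_rates",
    "POP_FLOOR",
    "TUMOR_FLOOR",
    "PERIODIC_TOL",
]

#: Positivity floor for power-law evaluation.  Negative exponents (g21 < 0)
#: diverge at zero, so integration clips populations at this floor.
POP_FLOOR = 1e-12

#: Floor used inside log(L_T / T) when the tumor decays toward extinction.
TUMOR_FLOOR = 1e-12

#: Half-width of the band |max Re eig| <= tol classified as periodic.
PERIODIC_TOL = 1e-10


class ParameterError(ValueError):
    """A parameter value violates its sign/positivity constraint."""


class DomainError(ValueError):
    """A state value is outside the domain of the model equations."""


class DegenerateParameterError(ParameterError):
    """The exponent determinant vanishes; no unique nontrivial steady state."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class RemodelingParams:
    """Constants of the normal (tumor-free) remodeling model.

    Parameters
    ----------
    alpha1, alpha2 : float
        Production rate constants for osteoclasts / osteoblasts (per day).
    beta1, beta2 : float
        Removal rate constants (per day).
    g11, g12, g21, g22 : float
        Autocrine/paracrine signaling exponents.  Sign conventions:
        ``g11 > 0``, ``g12 > 0``, ``g21 < 0``, ``g22 >= 0``.
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    g11: float
    g12: float
    g21: float
    g22: float

    def __post_init__(self) -> None:
        _require(self.alpha1 > 0, f"alpha1 must be > 0, got {self.alpha1}")
        _require(self.alpha2 > 0, f"alpha2 must be > 0, got {self.alpha2}")
        _require(self.beta1 > 0, f"beta1 must be > 0, got {self.beta1}")
        _require(self.beta2 > 0, f"beta2 must be > 0, got {self.beta2}")
        _require(self.g11 > 0, f"g11 must be > 0, got {self.g11}")
        _require(self.g12 > 0, f"g12 must be > 0, got {self.g12}")
        _require(self.g21 < 0, f"g21 must be < 0, got {self.g21}")
        _require(self.g22 >= 0, f"g22 must be >= 0, got {self.g22}")

    @property
    def exponents(self) -> "EffectiveExponents":
        """Baseline exponents packaged as :class:`EffectiveExponents`."""
        return EffectiveExponents(self.g11, self.g12, self.g21, self.g22)


@dataclass(frozen=True)
class TumorParams:
    """Gompertz tumor constants and exponent-perturbation weights.

    ``gamma_T`` is the Gompertz growth constant (per day) and ``L_T`` the
    maximum (carrying-capacity) tumor density.  The nonnegative weights
    ``r11, r12, r21, r22`` scale how strongly tumor burden ``T/L_T``
    perturbs the corresponding signaling exponent.
    """

    gamma_T: float
    L_T: float
    r11: float = 0.0
    r12: float = 0.0
    r21: float = 0.0
    r22: float = 0.0

    def __post_init__(self) -> None:
        _require(self.gamma_T > 0, f"gamma_T must be > 0, got {self.gamma_T}")
        _require(self.L_T > 0, f"L_T must be > 0, got {self.L_T}")
        for name in ("r11", "r12", "r21", "r22"):
            v = getattr(self, name)
            _require(v >= 0, f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class TreatmentParams:
    """Step-function treatment forcing.

    For ``t >= t_start`` the osteoblast removal coefficient becomes
    ``beta2 - v1`` (net osteoblast promotion) and the Gompertz growth
    constant becomes ``gamma_T - v2`` (tumor inhibition; the tumor is
    driven to extinction when ``v2 > gamma_T``).
    """

    v1: float = 0.0
    v2: float = 0.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        _require(self.v1 >= 0, f"v1 must be >= 0, got {self.v1}")
        _require(self.v2 >= 0, f"v2 must be >= 0, got {self.v2}")
        _require(self.t_start >= 0, f"t_start must be >= 0, got {self.t_start}")

    def validate_against(self, p: RemodelingParams) -> None:
        """Check that the forced osteoblast removal rate stays positive."""
        if self.v1 >= p.beta2:
            raise ParameterError(
                f"v1 ({self.v1}) must be < beta2 ({p.beta2}): the forced "
                "osteoblast removal rate beta2 - v1 must remain positive"
            )


@dataclass(frozen=True)
class BoneMassParams:
    """Constants of the bone-mass bookkeeping equation.

    Bone mass changes according to the excursions of the cell populations
    above their reference (normal nontrivial steady-state) levels::

        dz/dt = -k1 * max(0, C - C_ref) + k2 * max(0, B - B_ref)

    ``C_ref``/``B_ref`` default to the tumor-free nontrivial steady state of
    the accompanying :class:`RemodelingParams` when left unset.  ``k1`` and
    ``k2`` are conventionally tied by ``k1 = r * R`` and ``k2 = r`` with
    ``R`` the oscillation period and ``r`` set by the desired bone-mass
    oscillation amplitude (see :func:`osteodyn.simulate.calibrate_bone_weights`).
    """

    k1: float
    k2: float
    z0: float = 100.0
    C_ref: Optional[float] = None
    B_ref: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.k1 >= 0, f"k1 must be >= 0, got {self.k1}")
        _require(self.k2 >= 0, f"k2 must be >= 0, got {self.k2}")
        _require(self.z0 >= 0, f"z0 must be >= 0, got {self.z0}")
        if self.C_ref is not None:
            _require(self.C_ref > 0, f"C_ref must be > 0, got {self.C_ref}")
        if self.B_ref is not None:
            _require(self.B_ref > 0, f"B_ref must be > 0, got {self.B_ref}")

    def references(self, p: RemodelingParams) -> Tuple[float, float]:
        """Resolve (C_ref, B_ref), defaulting to the tumor-free steady state."""
        if self.C_ref is not None and self.B_ref is not None:
            return self.C_ref, self.B_ref
        Cbar, Bbar = steady_state(p)
        return (
            self.C_ref if self.C_ref is not None else Cbar,
            self.B_ref if self.B_ref is not None else Bbar,
        )


@dataclass(frozen=True)
class State0D:
    """Point state of the zero-dimensional model."""

    C: float
    B: float
    T: Optional[float] = None
    z: Optional[float] = None

    def __post_init__(self) -> None:
        _require(self.C > 0, f"C must be > 0, got {self.C}")
        _require(self.B > 0, f"B must be > 0, got {self.B}")
        if self.T is not None:
            _require(self.T >= 0, f"T must be >= 0, got {self.T}")
        if self.z is not None:
            _require(self.z >= 0, f"z must be >= 0, got {self.z}")


@dataclass(frozen=True)
class EffectiveExponents:
    """Signaling exponents, possibly tumor-modified."""

    e11: float
    e12: float
    e21: float
    e22: float

    def gamma(self) -> float:
        """Exponent determinant ``e12*e21 - (1 - e11)*(1 - e22)``."""
        return self.e12 * self.e21 - (1.0 - self.e11) * (1.0 - self.e22)


@dataclass(frozen=True)
class StabilityReport:
    """Steady state and linear-stability classification.

    ``psi_or_phi`` is the trace-form criterion
    ``beta1*(e11 - 1) + beta2*(e22 - 1)`` (called Psi without tumor and Phi
    with tumor); ``max_re_eig`` is the maximum real part of the Jacobian
    eigenvalues (equal to half the trace for a complex-conjugate pair).
    ``regime`` is ``"damped"``, ``"periodic"`` or ``"unstable"`` according
    to the sign of ``max_re_eig`` against ``tolerance``.
    """

    Cbar: float
    Bbar: float
    Gamma: float
    psi_or_phi: float
    max_re_eig: float
    regime: str
    tolerance: float
    eigenvalues: Tuple[complex, complex]
    exponents: EffectiveExponents


# ---------------------------------------------------------------------------
# Right-hand sides

def effective_exponents(
    p: RemodelingParams, tp: TumorParams, T: float
) -> EffectiveExponents:
    """Tumor-modified signaling exponents at tumor density ``T``.

    The tumor increases osteoclast autocrine promotion, weakens both
    paracrine channels and lowers osteoblast autocrine signaling::

        e11 = g11 * (1 + r11 * T/L_T)
        e21 = g21 * (1 + r21 * T/L_T)
        e12 = g12 / (1 + r12 * T/L_T)
        e22 = g22 - r22 * T/L_T

    At ``T = 0`` the baseline exponents are recovered exactly.
    """
    if not 0.0 <= T <= tp.L_T:
        raise DomainError(f"tumor density T={T} outside [0, L_T={tp.L_T}]")
    u = T / tp.L_T
    return EffectiveExponents(
        e11=p.g11 * (1.0 + tp.r11 * u),
        e12=p.g12 / (1.0 + tp.r12 * u),
        e21=p.g21 * (1.0 + tp.r21 * u),
        e22=p.g22 - tp.r22 * u,
    )


def power_law_rates(C, B, p: RemodelingParams, e: EffectiveExponents, floor: float = POP_FLOOR):
    """Vectorized production-minus-removal rates for (C, B).

    Populations are clipped at ``floor`` before exponentiation so that the
    negative exponent ``e21`` never divides by zero.  No domain validation;
    this is the integration kernel behind :func:`rhs_normal` and friends.
    """
    Cc = np.maximum(C, floor)
    Bc = np.maximum(B, floor)
    dC = p.alpha1 * Cc ** e.e11 * Bc ** e.e21 - p.beta1 * Cc
    dB = p.alpha2 * Cc ** e.e12 * Bc ** e.e22 - p.beta2 * Bc
    return dC, dB


def _check_state(C: float, B: float) -> None:
    if not (np.all(np.asarray(C) > 0) and np.all(np.asarray(B) > 0)):
        raise DomainError(
            f"populations must be positive (power laws with negative "
            f"exponents are undefined otherwise); got C={C}, B={B}"
        )


def rhs_normal(C, B, p: RemodelingParams):
    """Time derivatives (dC/dt, dB/dt) of the tumor-free model."""
    _check_state(C, B)
    return power_law_rates(C, B, p, p.exponents)


def gompertz_rate(T, gamma_T: float, L_T: float):
    """Gompertz growth rate ``gamma_T * T * log(L_T / T)``.

    Continuous at the origin: the rate is 0 at ``T = 0``; for positive ``T``
    below :data:`TUMOR_FLOOR` the logarithm is evaluated at the floor.
    """
    T = np.asarray(T, dtype=float)
    rate = gamma_T * T * np.log(L_T / np.maximum(T, TUMOR_FLOOR))
    return np.where(T > 0, rate, 0.0)


def rhs_tumor(C, B, T, p: RemodelingParams, tp: TumorParams):
    """Time derivatives (dC/dt, dB/dt, dT/dt) of the tumor-coupled model."""
    _check_state(C, B)
    if np.any(np.asarray(T) < 0) or np.any(np.asarray(T) > tp.L_T):
        raise DomainError(f"tumor density T={T} outside [0, L_T={tp.L_T}]")
    e = EffectiveExponents(
        e11=p.g11 * (1.0 + tp.r11 * np.asarray(T) / tp.L_T),
        e12=p.g12 / (1.0 + tp.r12 * np.asarray(T) / tp.L_T),
        e21=p.g21 * (1.0 + tp.r21 * np.asarray(T) / tp.L_T),
        e22=p.g22 - tp.r22 * np.asarray(T) / tp.L_T,
    )
    dC, dB = power_law_rates(C, B, p, e)
    dT = gompertz_rate(T, tp.gamma_T, tp.L_T)
    return dC, dB, dT


def rhs_treated(
    C,
    B,
    T,
    t: float,
    p: RemodelingParams,
    tp: TumorParams,
    trt: TreatmentParams,
):
    """Time derivatives of the treated tumor model at time ``t``.

    For ``t < t_start`` this is identical to :func:`rhs_tumor`; afterwards
    the osteoblast removal rate is ``beta2 - v1`` and the Gompertz constant
    is ``gamma_T - v2``.
    """
    trt.validate_against(p)
    dC, dB, dT = rhs_tumor(C, B, T, p, tp)
    if t >= trt.t_start:
        Bc = np.maximum(B, POP_FLOOR)
        dB = dB + trt.v1 * Bc
        Tarr = np.asarray(T, dtype=float)
        dT = dT - np.where(
            Tarr > 0, trt.v2 * Tarr * np.log(tp.L_T / np.maximum(Tarr, TUMOR_FLOOR)), 0.0
        )
    return dC, dB, dT


# ---------------------------------------------------------------------------
# Steady states and stability

def steady_state(
    p: RemodelingParams, e: Optional[EffectiveExponents] = None
) -> Tuple[float, float]:
    """Closed-form nontrivial steady state (Cbar, Bbar).

    With ``Gamma = e12*e21 - (1-e11)*(1-e22)``::

        Cbar = (beta1/alpha1)**((1-e22)/Gamma) * (beta2/alpha2)**(e21/Gamma)
        Bbar = (beta1/alpha1)**(e12/Gamma)    * (beta2/alpha2)**((1-e11)/Gamma)

    Raises :class:`DegenerateParameterError` when ``Gamma`` vanishes.
    """
    if e is None:
        e = p.exponents
    Gamma = e.gamma()
    if Gamma == 0.0:
        raise DegenerateParameterError(
            "exponent determinant Gamma = e12*e21 - (1-e11)*(1-e22) is zero; "
            "no unique nontrivial steady state"
        )
    q1 = p.beta1 / p.alpha1
    q2 = p.beta2 / p.alpha2
    Cbar = q1 ** ((1.0 - e.e22) / Gamma) * q2 ** (e.e21 / Gamma)
    Bbar = q1 ** (e.e12 / Gamma) * q2 ** ((1.0 - e.e11) / Gamma)
    return Cbar, Bbar


def jacobian_at(
    p: RemodelingParams,
    Cbar: float,
    Bbar: float,
    e: Optional[EffectiveExponents] = None,
) -> np.ndarray:
    """2x2 Jacobian of the (C, B) subsystem at (Cbar, Bbar).

    Obtained by differentiating the two power-law equations.  At the
    nontrivial steady state the diagonal reduces to ``beta1*(e11 - 1)`` and
    ``beta2*(e22 - 1)``.
    """
    if e is None:
        e = p.exponents
    _check_state(Cbar, Bbar)
    pc = p.alpha1 * Cbar ** e.e11 * Bbar ** e.e21  # osteoclast production
    pb = p.alpha2 * Cbar ** e.e12 * Bbar ** e.e22  # osteoblast production
    return np.array(
        [
            [e.e11 * pc / Cbar - p.beta1, e.e21 * pc / Bbar],
            [e.e12 * pb / Cbar, e.e22 * pb / Bbar - p.beta2],
        ]
    )


def stability_report(
    p: RemodelingParams,
    tp: Optional[TumorParams] = None,
    T_eval: Optional[float] = None,
    tolerance: float = PERIODIC_TOL,
) -> StabilityReport:
    """Classify the nontrivial steady state as damped / periodic / unstable.

    Without a tumor the baseline exponents are used and ``psi_or_phi`` is the
    criterion Psi; with a tumor the exponents are evaluated at ``T_eval``
    (defaulting to the carrying capacity ``L_T``) and the criterion is Phi.
    For a complex-conjugate eigenvalue pair ``max_re_eig`` equals exactly
    half the trace.
    """
    if tp is None:
        e = p.exponents
    else:
        if T_eval is None:
            T_eval = tp.L_T
        e = effective_exponents(p, tp, T_eval)
    Cbar, Bbar = steady_state(p, e)
    J = jacobian_at(p, Cbar, Bbar, e)
    trace = p.beta1 * (e.e11 - 1.0) + p.beta2 * (e.e22 - 1.0)
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = trace * trace - 4.0 * det
    if disc < 0.0:
        # complex pair: real part is exactly trace/2
        sq = math.sqrt(-disc) / 2.0
        eigs = (complex(trace / 2.0, sq), complex(trace / 2.0, -sq))
        max_re = trace / 2.0
    else:
        sq = math.sqrt(disc) / 2.0
        eigs = (complex(trace / 2.0 + sq), complex(trace / 2.0 - sq))
        max_re = trace / 2.0 + sq
    if max_re < -tolerance:
        regime = "damped"
    elif max_re > tolerance:
        regime = "unstable"
    else:
        regime = "periodic"
    return StabilityReport(
        Cbar=Cbar,
        Bbar=Bbar,
        Gamma=e.gamma(),
        psi_or_phi=trace,
        max_re_eig=max_re,
        regime=regime,
        tolerance=tolerance,
        eigenvalues=eigs,
        exponents=e,
    )
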