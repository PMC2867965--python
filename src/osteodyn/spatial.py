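"""One-dimensional spatial extension on Omega = [0, 1].

Osteoclasts, osteoblasts, tumor cells and bone mass diffuse weakly along a
one-dimensional bone-surface coordinate while reacting locally exactly as
in the zero-dimensional models.  The PDE system is discretized by the
method of lines: second-order central differences on a uniform closed grid
with zero-flux (Neumann) boundaries via ghost-node reflection, integrated
by the same adaptive Runge-Kutta solver as the 0-D runs.  The small
diffusion coefficients represent stochasticity in the local dynamics, not
physical cell migration, so spatially uniform initial data reproduce the
0-D trajectory at every node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from .model import (
    POP_FLOOR,
    TUMOR_FLOOR,
    BoneMassParams,
    ParameterError,
    RemodelingParams,
    TreatmentParams,
    TumorParams,
)
from .simulate import IntegrationError, SimSpec, bone_mass_rhs

__all__ = [
    "SpatialParams",
    "GridSpec",
    "FieldTrajectory",
    "laplacian_neumann",
    "ic_bumps",
    "simulate_pde",
    "bone_mass_field",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpatialParams:
    """Diffusion coefficients and optional bone-weight profiles.

    ``sigma1``/``sigma2`` diffuse the osteoclast/osteoblast fields,
    ``sigma3`` smooths the bone mass and ``sigma4`` spreads the tumor.  The
    optional ``k1``/``k2`` profiles override the scalar bone weights of
    :class:`~osteodyn.model.BoneMassParams` node-wise (constant profiles by
    default).
    """

    sigma1: float = 1e-6
    sigma2: float = 1e-6
    sigma3: float = 1e-6
    sigma4: float = 1e-6
    k1: Optional[Union[float, np.ndarray]] = None
    k2: Optional[Union[float, np.ndarray]] = None

    def __post_init__(self) -> None:
        for name in ("sigma1", "sigma2", "sigma3", "sigma4"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("k1", "k2"):
            prof = getattr(self, name)
            if prof is not None and np.any(np.asarray(prof) <= 0):
                raise ParameterError(f"{name} profile must be strictly positive")


@dataclass(frozen=True)
class GridSpec:
    """Uniform closed grid on [0, 1] with both endpoints included."""

    n: int = 101

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ParameterError(f"grid needs at least 3 nodes, got {self.n}")

    @property
    def h(self) -> float:
        return 1.0 / (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n)


@dataclass
class FieldTrajectory:
    """Sampled space-time solution: arrays of shape (n_times, n_nodes)."""

    times: np.ndarray
    x: np.ndarray
    C: np.ndarray
    B: np.ndarray
    T: Optional[np.ndarray] = None
    z: Optional[np.ndarray] = None
    metadata: Dict = field(default_factory=dict)


def laplacian_neumann(f: np.ndarray, h: float) -> np.ndarray:
    """Second central difference with zero-flux ends.

    Ghost nodes are reflections (``f[-1] = f[1]``, ``f[n] = f[n-2]``), so
    boundary rows are ``2*(f[1] - f[0])/h**2`` and ``2*(f[n-2] - f[n-1])/h**2``
    and the discrete integral of the Laplacian telescopes to zero.
    """
    f = np.asarray(f, dtype=float)
    out = np.empty_like(f)
    out[1:-1] = f[:-2] - 2.0 * f[1:-1] + f[2:]
    out[0] = 2.0 * (f[1] - f[0])
    out[-1] = 2.0 * (f[-2] - f[-1])
    return out / (h * h)


def ic_bumps(
    grid: GridSpec,
    baseline: float,
    centers: Sequence[float] = (),
    amplitudes: Sequence[float] = (),
    width: float = 0.05,
) -> np.ndarray:
    """Constant baseline plus Gaussian bumps.

    Used to seed localized elevations: remodeling events (osteoclasts
    raised above the steady state at discrete sites) or a tumor confined to
    one side of the domain.
    """
    if width <= 0:
        raise ParameterError(f"bump width must be > 0, got {width}")
    if len(centers) != len(amplitudes):
        raise ValueError("centers and amplitudes must have equal length")
    x = grid.x
    out = np.full(grid.n, float(baseline))
    for c, a in zip(centers, amplitudes):
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"bump center {c} outside [0, 1]")
        out += a * np.exp(-0.5 * ((x - c) / width) ** 2)
    return out


def _profiles(sp: SpatialParams, bp: Optional[BoneMassParams], n: int):
    k1 = sp.k1 if sp.k1 is not None else (bp.k1 if bp else 0.0)
    k2 = sp.k2 if sp.k2 is not None else (bp.k2 if bp else 0.0)
    return np.broadcast_to(np.asarray(k1, float), (n,)), np.broadcast_to(
        np.asarray(k2, float), (n,)
    )


def _make_field_rhs(p, tp, trt, bp, sp, grid, refs, treated_on: bool):
    n = grid.n
    h = grid.h
    has_T = tp is not None
    has_z = bp is not None
    b2 = p.beta2 - (trt.v1 if treated_on else 0.0)
    gam = (tp.gamma_T - (trt.v2 if treated_on else 0.0)) if has_T else 0.0
    k1x, k2x = _profiles(sp, bp, n)

    def rhs(t, y):
        C = np.maximum(y[:n], POP_FLOOR)
        B = np.maximum(y[n : 2 * n], POP_FLOOR)
        i = 2 * n
        if has_T:
            T = y[i : i + n]
            i += n
            u = np.clip(T, 0.0, tp.L_T) / tp.L_T
            e11 = p.g11 * (1.0 + tp.r11 * u)
            e12 = p.g12 / (1.0 + tp.r12 * u)
            e21 = p.g21 * (1.0 + tp.r21 * u)
            e22 = p.g22 - tp.r22 * u
            dT = np.where(
                T > 0.0, gam * T * np.log(tp.L_T / np.maximum(T, TUMOR_FLOOR)), 0.0
            )
            dT += sp.sigma4 * laplacian_neumann(T, h)
        else:
            e11, e12, e21, e22 = p.g11, p.g12, p.g21, p.g22
        dC = p.alpha1 * C ** e11 * B ** e21 - p.beta1 * C + sp.sigma1 * laplacian_neumann(C, h)
        dB = p.alpha2 * C ** e12 * B ** e22 - b2 * B + sp.sigma2 * laplacian_neumann(B, h)
        parts = [dC, dB]
        if has_T:
            parts.append(dT)
        if has_z:
            z = y[i : i + n]
            dz = (
                -k1x * np.maximum(0.0, C - refs[0])
                + k2x * np.maximum(0.0, B - refs[1])
                + sp.sigma3 * laplacian_neumann(z, h)
            )
            dz = np.where((z <= 0.0) & (dz < 0.0), 0.0, dz)
            parts.append(dz)
        return np.concatenate(parts)

    return rhs


def simulate_pde(
    p: RemodelingParams,
    ics: Dict[str, np.ndarray],
    grid: GridSpec,
    sp: SpatialParams,
    spec: Optional[SimSpec] = None,
    tp: Optional[TumorParams] = None,
    trt: Optional[TreatmentParams] = None,
    bp: Optional[BoneMassParams] = None,
) -> FieldTrajectory:
    """Method-of-lines integration of the 1-D reaction-diffusion system.

    ``ics`` maps variable names (``"C"``, ``"B"``, optionally ``"T"`` and
    ``"z"``) to initial fields of length ``grid.n``.  Reaction terms at each
    node are identical to the corresponding 0-D variant; treatment runs are
    restarted at ``t_start`` as in the 0-D integrator.
    """
    spec = spec or SimSpec()
    if trt is not None:
        if tp is None:
            raise ValueError("treatment requires tumor parameters")
        trt.validate_against(p)
    has_T = tp is not None
    has_z = bp is not None
    n = grid.n

    fields = [np.asarray(ics["C"], float), np.asarray(ics["B"], float)]
    if has_T:
        fields.append(np.asarray(ics.get("T", np.zeros(n)), float))
    if has_z:
        fields.append(np.asarray(ics.get("z", np.full(n, bp.z0)), float))
    for f in fields:
        if f.shape != (n,):
            raise ValueError(f"initial field shape {f.shape} != ({n},)")
    if np.any(fields[0] <= 0) or np.any(fields[1] <= 0):
        raise ValueError("initial cell fields must be strictly positive")
    y0 = np.concatenate(fields)

    refs = bp.references(p) if bp is not None else (None, None)
    treated_split = trt is not None and spec.t0 < trt.t_start < spec.t_end

    def factory(k):
        on = trt is not None and (k == 1 if treated_split else trt.t_start <= spec.t0)
        return _make_field_rhs(p, tp, trt, bp, sp, grid, refs, treated_on=on)

    from .simulate import _integrate_segments

    breakpoints = [trt.t_start] if treated_split else []
    log.info(
        "integrating %d-node field system over [%g, %g]", n, spec.t0, spec.t_end
    )
    ts, ys, nfev = _integrate_segments(factory, y0, spec, breakpoints)

    i = 2 * n
    T = z = None
    if has_T:
        T = ys[:, i : i + n]
        i += n
    if has_z:
        z = np.maximum(ys[:, i : i + n], 0.0)
    return FieldTrajectory(
        times=ts,
        x=grid.x,
        C=ys[:, :n],
        B=ys[:, n : 2 * n],
        T=T,
        z=z,
        metadata={
            "params": p,
            "tumor": tp,
            "treatment": trt,
            "bone": bp,
            "spatial": sp,
            "grid": grid,
            "refs": refs,
            "spec": spec,
            "nfev": nfev,
        },
    )


def bone_mass_field(
    ft: FieldTrajectory,
    sp: SpatialParams,
    bp: BoneMassParams,
    z0: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Bone-mass field driven by stored (C, B) fields.

    Integrates ``dz/dt = sigma3 * Lap(z) - k1(x)*max(0, C - C_ref)
    + k2(x)*max(0, B - B_ref)`` with no-flux ends, interpolating the
    sampled cell fields cubically in time.  Returns ``z`` with the shape of
    ``ft.C``.  Accuracy is limited by the trajectory's sampling density;
    the jointly integrated ``z`` from :func:`simulate_pde` is the primary
    path.
    """
    p = ft.metadata.get("params")
    grid: GridSpec = ft.metadata.get("grid") or GridSpec(ft.C.shape[1])
    refs = bp.references(p) if p is not None else (bp.C_ref, bp.B_ref)
    if refs[0] is None or refs[1] is None:
        raise ValueError("reference levels unavailable: set C_ref/B_ref or store params")
    n = grid.n
    if ft.C.shape[1] != n:
        raise ValueError("field trajectory width does not match grid")
    k1x, k2x = _profiles(sp, bp, n)
    kind = "cubic" if len(ft.times) >= 4 else "linear"
    C_of_t = interp1d(ft.times, ft.C, axis=0, kind=kind, assume_sorted=True)
    B_of_t = interp1d(ft.times, ft.B, axis=0, kind=kind, assume_sorted=True)

    def rhs(t, z):
        dz = (
            -k1x * np.maximum(0.0, C_of_t(t) - refs[0])
            + k2x * np.maximum(0.0, B_of_t(t) - refs[1])
            + sp.sigma3 * laplacian_neumann(z, grid.h)
        )
        return np.where((z <= 0.0) & (dz < 0.0), 0.0, dz)

    z_init = np.asarray(z0, float) if z0 is not None else np.full(n, bp.z0)
    sol = solve_ivp(
        rhs,
        (ft.times[0], ft.times[-1]),
        z_init,
        t_eval=ft.times,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise IntegrationError(
            f"bone-mass field integration failed: {sol.message}",
            t=sol.t[-1] if len(sol.t) else ft.times[0],
            y=sol.y[:, -1] if sol.y.size else z_init,
        )
    return np.maximum(sol.y.T, 0.0)
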