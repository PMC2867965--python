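"""Registry of published figure scenarios and the (r11, r22) regime sweep.

Each scenario bundles the printed parameter set of one simulation figure
into a runnable fixture.  Values not printed in the captions (initial bone
mass for the 0-D tumor runs, bump geometry of the spatial initial
conditions, run lengths) are documented defaults flagged ``approximate``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    BoneMassParams,
    RemodelingParams,
    State0D,
    TreatmentParams,
    TumorParams,
    stability_report,
    steady_state,
)
from .simulate import SimSpec, Trajectory, simulate
from .spatial import FieldTrajectory, GridSpec, SpatialParams, ic_bumps, simulate_pde

__all__ = [
    "Scenario",
    "RegimeSurface",
    "ScenarioNotFoundError",
    "get_scenario",
    "scenario_names",
    "run_scenario",
    "build_ics",
    "phi_surface",
    "zero_contour",
]

#: Sentinel baseline meaning "the tumor-free nontrivial steady state".
STEADY = "steady"


class ScenarioNotFoundError(KeyError):
    """Unknown scenario name; the message lists the registered ones."""


@dataclass(frozen=True)
class Scenario:
    """A runnable parameter bundle tied to a published simulation figure."""

    name: str
    description: str
    p: RemodelingParams
    bp: Optional[BoneMassParams] = None
    tp: Optional[TumorParams] = None
    trt: Optional[TreatmentParams] = None
    sp: Optional[SpatialParams] = None
    grid: Optional[GridSpec] = None
    sim: SimSpec = dc_field(default_factory=SimSpec)
    init: Optional[State0D] = None
    #: spatial initial conditions: variable -> {"baseline": float | "steady",
    #: "bumps": [(center, amplitude, width), ...]}
    ics: Optional[Dict[str, Dict]] = None
    #: names of fields whose values are documented defaults, not printed
    approximate: Tuple[str, ...] = ()

    @property
    def spatial(self) -> bool:
        return self.sp is not None


def _normal_params(g11: float) -> RemodelingParams:
    return RemodelingParams(
        alpha1=3.0, alpha2=4.0, beta1=0.2, beta2=0.02,
        g11=g11, g12=1.0, g21=-0.5, g22=0.0,
    )


def _tumor_fig4(r11: float, gamma_T: float = 0.005) -> TumorParams:
    return TumorParams(gamma_T=gamma_T, L_T=100.0, r11=r11, r12=0.0, r21=0.0, r22=0.2)


_BONE_FIG3 = BoneMassParams(k1=0.0748, k2=0.0006395, z0=100.0)
_BONE_SPATIAL = BoneMassParams(k1=0.45, k2=0.0048, z0=100.0)
_SIGMA = 1e-6


def _build_registry() -> Dict[str, Scenario]:
    reg: Dict[str, Scenario] = {}

    reg["fig2"] = Scenario(
        name="fig2",
        description=(
            "Single remodeling event: osteoclast steady state perturbed by +10 "
            "cell units; damped return to equilibrium (g11 = 0.5)."
        ),
        p=_normal_params(0.5),
        bp=BoneMassParams(k1=0.24, k2=0.0017, z0=100.0),
        init=State0D(C=11.06, B=212.13, z=100.0),
        sim=SimSpec(t_end=1000.0),
        approximate=("z0", "t_end"),
    )

    reg["fig3"] = Scenario(
        name="fig3",
        description=(
            "Regular periodic remodeling cycles (g11 = 1.1); bone mass "
            "oscillates about a normalized value of 100."
        ),
        p=_normal_params(1.1),
        bp=_BONE_FIG3,
        init=State0D(C=11.16, B=231.72, z=100.0),
        sim=SimSpec(t_end=1000.0),
        approximate=("z0", "t_end"),
    )

    reg["fig4_5"] = Scenario(
        name="fig4_5",
        description=(
            "Myeloma with r11 = .005: damped oscillations converging to the "
            "tumor steady state; tumor grows to capacity, bone mass lost."
        ),
        p=_normal_params(1.1),
        tp=_tumor_fig4(0.005),
        bp=_BONE_FIG3,
        init=State0D(C=15.0, B=316.0, T=1.0, z=100.0),
        # long enough for the tumor to reach capacity so the damped regime
        # dominates the amplitude trend
        sim=SimSpec(t_end=3000.0),
        approximate=("z0", "t_end"),
    )

    reg["fig6_7"] = Scenario(
        name="fig6_7",
        description=(
            "Myeloma with r11 = .02: unstable oscillations of growing "
            "amplitude; bone mass decreases to zero."
        ),
        p=_normal_params(1.1),
        tp=_tumor_fig4(0.02),
        bp=_BONE_FIG3,
        init=State0D(C=8.46, B=340.52, T=1.0, z=100.0),
        sim=SimSpec(t_end=3000.0),
        approximate=("z0", "t_end"),
    )

    reg["fig9_10"] = Scenario(
        name="fig9_10",
        description=(
            "Proteasome-inhibitor treatment of the r11 = .005 tumor from "
            "t_start = 600: tumor extinguished, cycles and bone mass recover."
        ),
        p=_normal_params(1.1),
        tp=_tumor_fig4(0.005),
        trt=TreatmentParams(v1=0.001, v2=0.008, t_start=600.0),
        bp=_BONE_FIG3,
        init=State0D(C=13.0, B=300.0, T=1.0, z=100.0),
        sim=SimSpec(t_end=2500.0),
        approximate=("z0", "t_end"),
    )

    bumps_C = {
        "baseline": STEADY,
        "bumps": [(0.2, 10.0, 0.05), (0.5, 10.0, 0.05), (0.8, 10.0, 0.05)],
    }
    reg["fig12_13"] = Scenario(
        name="fig12_13",
        description=(
            "Spatial normal remodeling: osteoclasts elevated at multiple "
            "sites; sustained spatial and temporal cycles about the steady state."
        ),
        p=_normal_params(1.1),
        bp=_BONE_SPATIAL,
        sp=SpatialParams(sigma1=_SIGMA, sigma2=_SIGMA, sigma3=_SIGMA),
        grid=GridSpec(101),
        sim=SimSpec(t_end=1000.0),
        ics={
            "C": bumps_C,
            "B": {"baseline": STEADY},
            "z": {"baseline": 100.0},
        },
        approximate=("bumps", "t_end"),
    )

    reg["fig14_16"] = Scenario(
        name="fig14_16",
        description=(
            "Spatial myeloma (gamma_T = .004): tumor seeded on the right side "
            "spreads to capacity; cycles collapse to the tumor steady state "
            "and bone mass is depleted throughout the domain."
        ),
        p=_normal_params(1.1),
        tp=_tumor_fig4(0.005, gamma_T=0.004),
        bp=_BONE_SPATIAL,
        sp=SpatialParams(sigma1=_SIGMA, sigma2=_SIGMA, sigma3=_SIGMA, sigma4=_SIGMA),
        grid=GridSpec(101),
        sim=SimSpec(t_end=3000.0),
        ics={
            "C": bumps_C,
            "B": {"baseline": STEADY},
            "T": {"baseline": 0.0, "bumps": [(1.0, 1.0, 0.1)]},
            "z": {"baseline": 100.0},
        },
        approximate=("bumps", "tumor seed", "t_end"),
    )

    reg["fig17_18"] = Scenario(
        name="fig17_18",
        description=(
            "Spatial myeloma with treatment from t_start = 600 (v1 = .0001, "
            "v2 = .006): tumor extinguished, cycles recover; bone lost on the "
            "right side is not recovered."
        ),
        p=_normal_params(1.1),
        tp=_tumor_fig4(0.005, gamma_T=0.004),
        trt=TreatmentParams(v1=0.0001, v2=0.006, t_start=600.0),
        bp=_BONE_SPATIAL,
        sp=SpatialParams(sigma1=_SIGMA, sigma2=_SIGMA, sigma3=_SIGMA, sigma4=_SIGMA),
        grid=GridSpec(101),
        sim=SimSpec(t_end=2500.0),
        ics={
            "C": bumps_C,
            "B": {"baseline": STEADY},
            "T": {"baseline": 0.0, "bumps": [(1.0, 1.0, 0.1)]},
            "z": {"baseline": 100.0},
        },
        approximate=("bumps", "tumor seed", "t_end"),
    )
    return reg


_REGISTRY = _build_registry()


def scenario_names() -> List[str]:
    return sorted(_REGISTRY)


def get_scenario(name: str) -> Scenario:
    """Return a copy of the registered scenario ``name``."""
    try:
        return copy.deepcopy(_REGISTRY[name])
    except KeyError:
        raise ScenarioNotFoundError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        ) from None


def build_ics(sc: Scenario, grid: Optional[GridSpec] = None) -> Dict[str, np.ndarray]:
    """Materialize a spatial scenario's declarative initial conditions."""
    if sc.ics is None:
        raise ValueError(f"scenario {sc.name!r} has no spatial initial conditions")
    grid = grid or sc.grid or GridSpec()
    Cbar, Bbar = steady_state(sc.p)
    out: Dict[str, np.ndarray] = {}
    for var, spec in sc.ics.items():
        base = spec.get("baseline", 0.0)
        if base == STEADY:
            base = {"C": Cbar, "B": Bbar}[var]
        bumps = spec.get("bumps", [])
        out[var] = ic_bumps(
            grid,
            base,
            centers=[b[0] for b in bumps],
            amplitudes=[b[1] for b in bumps],
            width=bumps[0][2] if bumps else 0.05,
        )
    return out


def run_scenario(
    name: str,
    sim: Optional[SimSpec] = None,
    grid: Optional[GridSpec] = None,
):
    """Run a registered scenario end-to-end.

    Returns a :class:`~osteodyn.simulate.Trajectory` for 0-D scenarios and a
    :class:`~osteodyn.spatial.FieldTrajectory` for spatial ones.  ``sim`` and
    ``grid`` override the stored defaults (e.g. to shorten or coarsen a run).
    """
    sc = get_scenario(name)
    spec = sim or sc.sim
    if sc.spatial:
        g = grid or sc.grid or GridSpec()
        ics = build_ics(sc, g)
        return simulate_pde(
            sc.p, ics, g, sc.sp, spec=spec, tp=sc.tp, trt=sc.trt, bp=sc.bp
        )
    return simulate(sc.p, sc.init, spec=spec, tp=sc.tp, trt=sc.trt, bp=sc.bp)


# ---------------------------------------------------------------------------
# Regime surface over the tumor perturbation weights

@dataclass
class RegimeSurface:
    """Maximum eigenvalue real part over a (r11, r22) grid.

    ``values[i, j]`` is the stability value at ``(r11[i], r22[j])``; the
    sign map separates damped (negative) from unstable (positive) regions.
    """

    r11: np.ndarray
    r22: np.ndarray
    values: np.ndarray

    @property
    def sign(self) -> np.ndarray:
        return np.sign(self.values)


def phi_surface(
    p: RemodelingParams,
    tp: TumorParams,
    r11: Sequence[float] = None,
    r22: Sequence[float] = None,
    resolution: int = 61,
) -> RegimeSurface:
    """Sweep the stability value over tumor perturbation weights.

    Each cell evaluates the maximum eigenvalue real part of the Jacobian at
    the tumor-capacity steady state (``T_eval = L_T``), with ``r12``/``r21``
    held at the base values.  The default window [0, 0.03] x [0, 0.4]
    brackets both published sample points and the damped/unstable boundary.
    """
    r11 = np.asarray(r11 if r11 is not None else np.linspace(0.0, 0.03, resolution))
    r22 = np.asarray(r22 if r22 is not None else np.linspace(0.0, 0.4, resolution))
    if np.any(r11 < 0) or np.any(r22 < 0):
        raise ValueError("perturbation weights must be nonnegative")
    vals = np.empty((len(r11), len(r22)))
    for i, a in enumerate(r11):
        for j, b in enumerate(r22):
            tpij = TumorParams(
                gamma_T=tp.gamma_T, L_T=tp.L_T,
                r11=float(a), r12=tp.r12, r21=tp.r21, r22=float(b),
            )
            vals[i, j] = stability_report(p, tpij, T_eval=tp.L_T).max_re_eig
    return RegimeSurface(r11=r11, r22=r22, values=vals)


def zero_contour(surface: RegimeSurface) -> np.ndarray:
    """Linear-interpolated zero crossings of the surface, row by row.

    For each fixed ``r22`` the crossing of ``max_re_eig = 0`` along ``r11``
    is located by linear interpolation between the bracketing grid cells.
    Returns an array of (r11, r22) points; empty when the surface has a
    single sign.
    """
    pts = []
    for j, b in enumerate(surface.r22):
        col = surface.values[:, j]
        s = np.sign(col)
        for i in range(len(col) - 1):
            if s[i] == 0.0:
                pts.append((surface.r11[i], b))
            elif s[i] * s[i + 1] < 0.0:
                f = col[i] / (col[i] - col[i + 1])
                pts.append((surface.r11[i] + f * (surface.r11[i + 1] - surface.r11[i]), b))
        if s[-1] == 0.0:
            pts.append((surface.r11[-1], b))
    return np.asarray(pts).reshape(-1, 2)
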