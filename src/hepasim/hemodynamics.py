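"""Reduced-order pulsatile flow on the arterial network.

Outlet flows are boundary conditions, so the instantaneous flow in any branch
is the inlet waveform times the summed flow fractions of the outlets
downstream of that branch (0D mass-conservation split).  Each branch carries
a quasi-steady laminar (Poiseuille) profile; blood rheology is shear-thinning
via the Carreau law.

The Carreau parameter defaults and the blood density are generic literature
values for blood, configurable through :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .boundary import OutletBC
from .vasculature import ArterialTree

__all__ = [
    "CarreauParams",
    "SimulationConfig",
    "WaveformParams",
    "inlet_waveform",
    "FlowField",
    "solve_branch_flows",
    "velocity_profile",
    "effective_viscosity",
    "downstream_fractions",
    "ML_MIN_TO_M3_S",
]

#: ml/min -> m^3/s
ML_MIN_TO_M3_S = 1e-6 / 60.0


@dataclass(frozen=True)
class CarreauParams:
    """Carreau shear-thinning viscosity parameters (SI)."""

    mu0: float = 0.056      # Pa s, zero-shear viscosity
    mu_inf: float = 0.0035  # Pa s, infinite-shear viscosity
    lam: float = 3.313      # s, relaxation time
    n: float = 0.3568       # power-law index

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.mu_inf <= 0 or self.lam < 0:
            raise ValueError("viscosities must be positive, lambda non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol and fluid constants for one transient simulation."""

    cardiac_period: float = 1.0          # s
    n_cycles: int = 4
    dt: float = 2e-3                     # s
    gravity: tuple[float, float, float] = (0.0, 0.0, -9.8)  # m/s^2
    blood_density: float = 1060.0        # kg/m^3
    viscosity_params: CarreauParams = field(default_factory=CarreauParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cardiac_period <= 0:
            raise ValueError("cardiac_period must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not self.dt < self.cardiac_period / 10.0:
            raise ValueError("dt must be < cardiac_period / 10")

    @property
    def total_time(self) -> float:
        return self.n_cycles * self.cardiac_period

    @property
    def gravity_vector(self) -> np.ndarray:
        return np.asarray(self.gravity, dtype=float)


@dataclass(frozen=True)
class WaveformParams:
    """Truncated Fourier pulse: mean * (1 + sum_k a_k sin(2*pi*k*t/T + phi_k)).

    Every pure-sine harmonic integrates to zero over a full period, so the
    cycle average equals the prescribed mean for any amplitudes/phases.
    """

    period: float = 1.0
    amplitudes: tuple[float, ...] = (0.3, 0.1)
    phases: tuple[float, ...] = (0.0, math.pi / 2.0)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if len(self.amplitudes) != len(self.phases):
            raise ValueError("amplitudes and phases must have equal length")
        if sum(abs(a) for a in self.amplitudes) >= 1.0:
            warnings.warn(
                "harmonic amplitudes may produce negative instantaneous flow",
                stacklevel=2,
            )

    @classmethod
    def constant(cls, period: float = 1.0) -> "WaveformParams":
        return cls(period=period, amplitudes=(), phases=())


def inlet_waveform(t, mean_flow: float, params: WaveformParams):
    """Pulsatile inlet flow (ml/min) at time(s) ``t``; cycle mean = mean_flow."""
    if mean_flow < 0:
        raise ValueError("mean_flow must be >= 0")
    t = np.asarray(t, dtype=float)
    shape = np.ones_like(t)
    for k, (a, phi) in enumerate(zip(params.amplitudes, params.phases), start=1):
        shape = shape + a * np.sin(2.0 * math.pi * k * t / params.period + phi)
    out = mean_flow * shape
    return float(out) if out.ndim == 0 else out


def downstream_fractions(tree: ArterialTree, bcs: list[OutletBC]) -> dict[str, float]:
    """Summed outlet flow fraction downstream of (and including) each branch."""
    frac_by_outlet = {bc.outlet_id: bc.flow_fraction for bc in bcs}
    if sorted(frac_by_outlet) != sorted(tree.outlet_ids):
        raise ValueError("outlet BCs do not match the tree's outlets")
    fractions: dict[str, float] = {}

    def accumulate(nid: str) -> float:
        node = tree.nodes[nid]
        if node.is_outlet:
            f = frac_by_outlet[nid]
        else:
            f = sum(accumulate(d) for d in node.daughter_ids)
        fractions[nid] = f
        return f

    accumulate(tree.root_id)
    return fractions


@dataclass
class FlowField:
    """Time-resolved branch flows from a prescribed-fraction 0D split."""

    tree: ArterialTree
    fractions: dict[str, float]  # branch -> downstream outlet-fraction sum
    mean_inlet_flow: float  # ml/min
    waveform: WaveformParams

    def inlet_flow(self, t):
        return inlet_waveform(t, self.mean_inlet_flow, self.waveform)

    def flow(self, branch_id: str, t):
        """Flow through a branch (ml/min)."""
        return self.fractions[branch_id] * self.inlet_flow(t)

    def flow_si(self, branch_id: str, t):
        """Flow through a branch (m^3/s)."""
        return self.flow(branch_id, t) * ML_MIN_TO_M3_S

    def mean_velocity(self, branch_id: str, t):
        """Cross-sectional mean axial velocity (m/s)."""
        r = self.tree.nodes[branch_id].radius
        return self.flow_si(branch_id, t) / (math.pi * r * r)


def solve_branch_flows(
    tree: ArterialTree,
    bcs: list[OutletBC],
    mean_inlet_flow: float | None = None,
    waveform: WaveformParams | None = None,
) -> FlowField:
    """Build the network flow field from outlet BCs and an inlet waveform.

    ``mean_inlet_flow`` defaults to the sum of the outlet flows, which is the
    inlet boundary condition; passing it explicitly allows non-dimensional
    studies.
    """
    if waveform is None:
        waveform = WaveformParams()
    fractions = downstream_fractions(tree, bcs)
    if mean_inlet_flow is None:
        mean_inlet_flow = sum(bc.flow_rate for bc in bcs)
    return FlowField(tree=tree, fractions=fractions,
                     mean_inlet_flow=float(mean_inlet_flow), waveform=waveform)


def velocity_profile(radius: float, flow_si: float, r) -> np.ndarray | float:
    """Poiseuille axial velocity u(r) = 2 U (1 - (r/R)^2), U = Q/(pi R^2)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > radius):
        raise ValueError("radial position must be within [0, branch radius]")
    u_mean = flow_si / (math.pi * radius * radius)
    out = 2.0 * u_mean * (1.0 - (r / radius) ** 2)
    return float(out) if out.ndim == 0 else out


def effective_viscosity(shear_rate, params: CarreauParams | None = None):
    """Carreau viscosity mu(shear) = mu_inf + (mu0-mu_inf)[1+(lam g)^2]^((n-1)/2)."""
    if params is None:
        params = CarreauParams()
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    mu = params.mu_inf + (params.mu0 - params.mu_inf) * (
        1.0 + (params.lam * g) ** 2) ** ((params.n - 1.0) / 2.0)
    return float(mu) if mu.ndim == 0 else mu


def poiseuille_pressure_drop(radius: float, length: float, flow_si: float,
                             params: CarreauParams | None = None) -> float:
    """Diagnostic Poiseuille pressure drop with Carreau viscosity.

    Viscosity is evaluated at the branch characteristic shear 8U/d.
    """
    u_mean = flow_si / (math.pi * radius**2)
    shear = 8.0 * abs(u_mean) / (2.0 * radius)
    mu = effective_viscosity(shear, params)
    return 8.0 * mu * length * flow_si / (math.pi * radius**4)
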