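"""Lagrangian microsphere transport through the arterial network.

Particles are injected during the first cardiac cycle and tracked for the
whole simulated window (default four cycles).  Each particle obeys Newton's
second law with Stokes drag against the local Poiseuille velocity plus net
gravity/buoyancy, integrated semi-implicitly with the global time step.
Particle position is tracked as (branch, axial coordinate, cross-section
coordinates); at a bifurcation the parent disc is partitioned by a chord
placed so that the Poiseuille flux on either side matches the daughter flow
fractions, and the particle follows the side it sits on.  Exits through the
truncated outlets are tallied per outlet; particles still inside at the end
are counted as residents and excluded from distribution numerators.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .hemodynamics import (
    ML_MIN_TO_M3_S,
    SimulationConfig,
    FlowField,
    effective_viscosity,
    inlet_waveform,
)
from .vasculature import ArterialTree, CatheterPlacement, branch_frame

__all__ = [
    "MicrosphereProperties",
    "ParticleState",
    "TransportResult",
    "injection_schedule",
    "step_particle",
    "bifurcation_assignment",
    "partition_offset",
    "flux_fraction_above",
    "flux_weighted_radii",
    "run_transport",
]


@dataclass(frozen=True)
class MicrosphereProperties:
    """Size and density of the injected microspheres (generic resin values)."""

    diameter: float = 32e-6  # m
    density: float = 1600.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("diameter and density must be > 0")

    def check_against_tree(self, tree: ArterialTree) -> None:
        if self.diameter >= 0.2 * tree.min_radius():
            raise ValueError(
                "microsphere diameter must be small versus the narrowest vessel"
            )


@dataclass
class ParticleState:
    """One microsphere: branch-local position plus a global velocity vector."""

    particle_id: int
    branch_id: str
    axial_position: float           # m along the branch
    cross_position: np.ndarray      # 2-vector in the cross-section plane, m
    velocity: np.ndarray            # 3-vector, m/s, global frame
    status: str = "in_transit"      # in_transit | exited | resident_at_end
    outlet_id: str | None = None

    def __post_init__(self) -> None:
        self.cross_position = np.asarray(self.cross_position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


@dataclass
class TransportResult:
    """Per-outlet exit tallies for one injection."""

    injected_count: int
    exit_counts: dict[str, int]
    resident_count: int
    seed: int | None = None
    n_cycles: int | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        if sum(self.exit_counts.values()) + self.resident_count != self.injected_count:
            raise ValueError("exits + residents must equal injected count")

    @property
    def exited_count(self) -> int:
        return self.injected_count - self.resident_count

    @property
    def exit_fraction(self) -> float:
        return self.exited_count / self.injected_count

    def to_json(self) -> str:
        return json.dumps({
            "injected_count": self.injected_count,
            "exit_counts": dict(sorted(self.exit_counts.items())),
            "resident_count": self.resident_count,
            "exit_fraction": self.exit_fraction,
            "seed": self.seed,
            "n_cycles": self.n_cycles,
            "dt": self.dt,
        }, indent=2)


# ---------------------------------------------------------------------------
# injection
# ---------------------------------------------------------------------------

def injection_schedule(
    n_particles: int,
    catheter: CatheterPlacement,
    cardiac_period: float,
    seed,
    vessel_radius: float,
    vessel_length: float = 0.0,
    frame: np.ndarray | None = None,
) -> list[tuple[float, ParticleState]]:
    """Release times and initial states for one injection.

    Release times are uniform over the first cardiac cycle.  Initial
    cross-section positions are uniform over the catheter lumen disc centered
    at the tip offset; the initial velocity is the injection velocity along
    the vessel axis.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    catheter.check_fits(vessel_radius)
    if frame is None:
        frame = branch_frame(np.array([1.0, 0.0, 0.0]))
    axis = frame[0]
    rng = np.random.default_rng(seed)

    release = np.sort(rng.uniform(0.0, cardiac_period, size=n_particles))
    center = catheter.radial_offset_fraction * vessel_radius * np.array(
        [math.cos(catheter.azimuth), math.sin(catheter.azimuth)])
    # uniform over the lumen disc
    rr = catheter.catheter_inner_radius * np.sqrt(rng.uniform(size=n_particles))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n_particles)
    cross = center + np.stack([rr * np.cos(th), rr * np.sin(th)], axis=1)
    axial0 = catheter.axial_fraction * vessel_length
    v0 = catheter.injection_velocity * axis

    return [
        (float(release[i]),
         ParticleState(
             particle_id=i,
             branch_id=catheter.vessel_id,
             axial_position=axial0,
             cross_position=cross[i].copy(),
             velocity=v0.copy(),
         ))
        for i in range(n_particles)
    ]


# ---------------------------------------------------------------------------
# single-particle dynamics
# ---------------------------------------------------------------------------

def _relaxation_time(props: MicrosphereProperties, viscosity: float) -> float:
    return props.density * props.diameter**2 / (18.0 * viscosity)


def step_particle(
    state: ParticleState,
    dt: float,
    fluid_velocity: np.ndarray,
    config: SimulationConfig,
    props: MicrosphereProperties,
    viscosity: float | None = None,
    frame: np.ndarray | None = None,
    radius: float | None = None,
) -> ParticleState:
    """Advance one in-transit particle by ``dt`` (semi-implicit drag update).

    dv/dt = (u_fluid - v)/tau + (1 - rho_f/rho_p) g,  tau = rho_p d^2/(18 mu).

    ``frame`` is the branch frame (rows axis, e1, e2); ``radius`` enables the
    wall clamp on the cross position.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if state.status != "in_transit":
        raise ValueError(f"particle {state.particle_id} is not in transit")
    if viscosity is None:
        viscosity = effective_viscosity(0.0, config.viscosity_params)
    if frame is None:
        frame = branch_frame(np.array([1.0, 0.0, 0.0]))
    u = np.asarray(fluid_velocity, dtype=float)
    tau = _relaxation_time(props, viscosity)
    g_eff = (1.0 - config.blood_density / props.density) * config.gravity_vector
    v_new = (state.velocity + dt * (u / tau + g_eff)) / (1.0 + dt / tau)
    if not np.all(np.isfinite(v_new)):
        raise RuntimeError(f"non-finite state for particle {state.particle_id}")

    axis, e1, e2 = frame
    axial = state.axial_position + float(np.dot(v_new, axis)) * dt
    cross = state.cross_position + dt * np.array(
        [float(np.dot(v_new, e1)), float(np.dot(v_new, e2))])
    if radius is not None:
        bound = radius - props.diameter / 2.0
        rn = float(np.linalg.norm(cross))
        if rn > bound:
            cross *= bound / rn
    return ParticleState(
        particle_id=state.particle_id,
        branch_id=state.branch_id,
        axial_position=max(axial, 0.0),
        cross_position=cross,
        velocity=v_new,
        status=state.status,
    )


# ---------------------------------------------------------------------------
# bifurcation partition
# ---------------------------------------------------------------------------

def flux_fraction_above(u: float) -> float:
    """Poiseuille flux fraction carried by the half-disc {x/R > u}.

    Closed form of (8 / 3 pi) * integral_u^1 (1 - x^2)^(3/2) dx.
    """
    u = min(max(u, -1.0), 1.0)

    def antider(x: float) -> float:
        s = math.sqrt(max(1.0 - x * x, 0.0))
        return x * s**3 / 4.0 + (3.0 / 8.0) * (x * s + math.asin(x))

    return (8.0 / (3.0 * math.pi)) * (antider(1.0) - antider(u))


def partition_offset(f1: float, tol: float = 1e-10) -> float:
    """Chord offset u* in [-1, 1] with flux fraction f1 above it (bisection)."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError("flow fraction must be in [0, 1]")
    lo, hi = -1.0, 1.0  # flux_fraction_above is decreasing: phi(-1)=1, phi(1)=0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if flux_fraction_above(mid) > f1:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _separation_axis(parent_frame: np.ndarray,
                     daughter_directions: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Unit 2-vector along which daughter 1 separates from daughter 2."""
    _, e1, e2 = parent_frame
    sep = np.asarray(daughter_directions[0], float) - np.asarray(
        daughter_directions[1], float)
    s2 = np.array([float(np.dot(sep, e1)), float(np.dot(sep, e2))])
    n = float(np.linalg.norm(s2))
    if n < 1e-9:
        warnings.warn(
            "degenerate daughter directions; falling back to the reference axis",
            stacklevel=2,
        )
        return np.array([1.0, 0.0])
    return s2 / n


def bifurcation_assignment(
    cross_position: np.ndarray,
    parent_radius: float,
    daughter_directions: tuple[np.ndarray, np.ndarray],
    flow_fractions: tuple[float, float],
    parent_frame: np.ndarray | None = None,
) -> int:
    """Deterministically pick the daughter (0 or 1) a particle enters.

    The parent disc is split by the chord perpendicular to the projected
    daughter-separation axis, placed so the Poiseuille flux on daughter 1's
    side equals its flow fraction.
    """
    f1, f2 = flow_fractions
    if abs(f1 + f2 - 1.0) > 1e-9:
        raise ValueError("daughter flow fractions must sum to 1")
    cross = np.asarray(cross_position, dtype=float)
    if float(np.linalg.norm(cross)) > parent_radius * (1.0 + 1e-12):
        raise ValueError("cross position lies outside the lumen")
    if parent_frame is None:
        axis = np.asarray(daughter_directions[0], float) + np.asarray(
            daughter_directions[1], float)
        axis = axis / np.linalg.norm(axis)
        parent_frame = branch_frame(axis)
    shat = _separation_axis(parent_frame, daughter_directions)
    s = float(np.dot(cross, shat)) / parent_radius
    return 0 if s > partition_offset(f1) else 1


def flux_weighted_radii(radius: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample radial positions with Poiseuille-flux weighting over a disc."""
    u = rng.uniform(size=n)
    return radius * np.sqrt(1.0 - np.sqrt(1.0 - u))


# ---------------------------------------------------------------------------
# full transport run
# ---------------------------------------------------------------------------

def run_transport(
    tree: ArterialTree,
    flow_field: FlowField,
    catheter: CatheterPlacement,
    config: SimulationConfig,
    props: MicrosphereProperties,
    n_particles: int = 10_000,
    seed: int | None = 0,
    release: str = "catheter",
    exit_warn_threshold: float = 0.95,
) -> TransportResult:
    """Simulate one injection through the network and tally outlet exits.

    ``release='catheter'`` seeds particles uniformly over the catheter lumen
    with the injection velocity; ``release='flux_weighted'`` seeds them
    flux-weighted over the root inlet disc moving with the local fluid, the
    configuration in which per-outlet exit fractions converge to the outlet
    flow fractions.
    """
    if release not in ("catheter", "flux_weighted"):
        raise ValueError("release must be 'catheter' or 'flux_weighted'")
    props.check_against_tree(tree)

    ids = sorted(tree.nodes)
    index = {nid: i for i, nid in enumerate(ids)}
    nb = len(ids)
    radius = np.array([tree.nodes[n].radius for n in ids])
    length = np.array([tree.nodes[n].length for n in ids])
    frac = np.array([flow_field.fractions[n] for n in ids])
    frames = np.stack([branch_frame(tree.nodes[n].direction) for n in ids])
    axis_b, e1_b, e2_b = frames[:, 0], frames[:, 1], frames[:, 2]
    is_outlet = np.array([tree.nodes[n].is_outlet for n in ids])

    # bifurcation partition precomputation (fractions are time-independent)
    d1_idx = np.full(nb, -1, dtype=int)
    d2_idx = np.full(nb, -1, dtype=int)
    u_star = np.zeros(nb)
    sep2d = np.zeros((nb, 2))
    for i, nid in enumerate(ids):
        dts = tree.nodes[nid].daughter_ids
        if len(dts) == 1:
            d1_idx[i] = index[dts[0]]
        elif len(dts) == 2:
            j1, j2 = index[dts[0]], index[dts[1]]
            d1_idx[i], d2_idx[i] = j1, j2
            fsum = frac[j1] + frac[j2]
            f1 = frac[j1] / fsum if fsum > 0 else 0.5
            u_star[i] = partition_offset(f1)
            sep2d[i] = _separation_axis(
                frames[i], (tree.nodes[dts[0]].direction,
                            tree.nodes[dts[1]].direction))

    ss = np.random.SeedSequence(seed)
    sched_seed, transit_seed = ss.spawn(2)
    rng = np.random.default_rng(transit_seed)

    if release == "catheter":
        cath_idx = index[catheter.vessel_id]
        schedule = injection_schedule(
            n_particles, catheter, config.cardiac_period, sched_seed,
            vessel_radius=float(radius[cath_idx]),
            vessel_length=float(length[cath_idx]),
            frame=frames[cath_idx],
        )
        branch0 = np.full(n_particles, cath_idx, dtype=int)
        release_t = np.array([t for t, _ in schedule])
        axial = np.array([s.axial_position for _, s in schedule])
        cross = np.stack([s.cross_position for _, s in schedule])
        vel = np.stack([s.velocity for _, s in schedule])
    else:
        srng = np.random.default_rng(sched_seed)
        root = index[tree.root_id]
        branch0 = np.full(n_particles, root, dtype=int)
        release_t = np.sort(srng.uniform(0.0, config.cardiac_period, n_particles))
        rr = flux_weighted_radii(float(radius[root]) - props.diameter / 2.0,
                                 n_particles, srng)
        th = srng.uniform(0.0, 2.0 * math.pi, n_particles)
        cross = np.stack([rr * np.cos(th), rr * np.sin(th)], axis=1)
        axial = np.zeros(n_particles)
        vel = np.zeros((n_particles, 3))  # relaxes to the local fluid in O(tau)

    branch = branch0.copy()
    UNRELEASED, TRANSIT, EXITED = 0, 1, 2
    status = np.full(n_particles, UNRELEASED, dtype=np.int8)
    outlet_of = np.full(n_particles, -1, dtype=int)

    dt = config.dt
    n_steps = int(round(config.total_time / dt))
    g_eff = (1.0 - config.blood_density / props.density) * config.gravity_vector
    rho_p, d_p = props.density, props.diameter
    bound = radius - d_p / 2.0

    def handle_crossings(idx_cross: np.ndarray) -> None:
        for i in idx_cross:
            while status[i] == TRANSIT and axial[i] >= length[branch[i]]:
                b = branch[i]
                if is_outlet[b]:
                    status[i] = EXITED
                    outlet_of[i] = b
                    break
                if d2_idx[b] < 0:  # pass-through node
                    nxt = d1_idx[b]
                else:
                    s = float(cross[i] @ sep2d[b]) / radius[b]
                    nxt = d1_idx[b] if s > u_star[b] else d2_idx[b]
                axial[i] = axial[i] - length[b]
                branch[i] = nxt
                # flux-weighted redistribution over the daughter disc keeps
                # each branch ensemble consistent with the local flow split
                rr = float(flux_weighted_radii(bound[nxt], 1, rng)[0])
                th = float(rng.uniform(0.0, 2.0 * math.pi))
                cross[i, 0] = rr * math.cos(th)
                cross[i, 1] = rr * math.sin(th)

    for k in range(n_steps + 1):
        t = k * dt
        np.putmask(status, (status == UNRELEASED) & (release_t <= t), TRANSIT)
        active = np.flatnonzero(status == TRANSIT)
        if active.size == 0:
            if np.all(status != UNRELEASED):
                break
            continue

        q_in = inlet_waveform(t, flow_field.mean_inlet_flow,
                              flow_field.waveform) * ML_MIN_TO_M3_S
        u_mean_b = frac * q_in / (math.pi * radius**2)
        shear_b = 4.0 * np.abs(u_mean_b) / radius
        mu_b = effective_viscosity(shear_b, config.viscosity_params)
        tau_b = rho_p * d_p**2 / (18.0 * mu_b)

        b = branch[active]
        r = np.linalg.norm(cross[active], axis=1)
        u_ax = 2.0 * u_mean_b[b] * (1.0 - (r / radius[b]) ** 2)
        u_fluid = axis_b[b] * u_ax[:, None]
        tau = tau_b[b][:, None]
        v = vel[active]
        v = (v + dt * (u_fluid / tau + g_eff)) / (1.0 + dt / tau)
        if not np.all(np.isfinite(v)):
            bad = active[~np.all(np.isfinite(v), axis=1)][0]
            raise RuntimeError(f"non-finite state for particle {bad}")
        vel[active] = v

        axial[active] = np.maximum(
            axial[active] + np.einsum("ij,ij->i", v, axis_b[b]) * dt, 0.0)
        cross[active, 0] += np.einsum("ij,ij->i", v, e1_b[b]) * dt
        cross[active, 1] += np.einsum("ij,ij->i", v, e2_b[b]) * dt
        rn = np.linalg.norm(cross[active], axis=1)
        over = rn > bound[b]
        if np.any(over):
            sel = active[over]
            cross[sel] *= (bound[branch[sel]] / rn[over])[:, None]

        crossed = active[axial[active] >= length[b]]
        if crossed.size:
            handle_crossings(crossed)

    exit_counts = {nid: 0 for nid in sorted(tree.outlet_ids)}
    for i in np.flatnonzero(status == EXITED):
        exit_counts[ids[outlet_of[i]]] += 1
    resident = int(np.sum(status != EXITED))

    result = TransportResult(
        injected_count=n_particles,
        exit_counts=exit_counts,
        resident_count=resident,
        seed=seed,
        n_cycles=config.n_cycles,
        dt=config.dt,
    )
    if result.exit_fraction < exit_warn_threshold:
        warnings.warn(
            f"only {result.exit_fraction:.1%} of injected microspheres exited "
            f"the domain (threshold {exit_warn_threshold:.0%})",
            stacklevel=2,
        )
    return result
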