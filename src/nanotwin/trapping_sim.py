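"""Overdamped Brownian dynamics of particle capture at the nanoprobe tip.

The tip apex sits at the origin and the field is radially symmetric about
it, so capture, release and retention reduce to radial dynamics plus
isotropic diffusion.  Dynamics are overdamped (particle Reynolds and
Stokes numbers are far below one at these scales): Euler-Maruyama,

    x += (F_dep / gamma) dt + sqrt(2 D dt) xi,   gamma = 6 pi eta a,
    D = kB T / gamma,

with reflecting walls at the simulation box and at the probe contact
surface.  A particle that reaches contact while the drive is on sticks and
co-moves with the probe; switching the drive off releases every particle
instantly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import KB
from .dep_physics import (
    DepDrive,
    DielectricBody,
    Medium,
    TipFieldModel,
    _force_prefactor,
)

__all__ = [
    "ParticleEnsemble",
    "BrownianConfig",
    "TrapSimResult",
    "diffusion_coefficient",
    "step_brownian",
    "run_trapping",
    "run_release",
    "run_translation",
    "success_surface",
    "make_cluster",
]

TRAP_REGION_RADIUS = 1.8e-6  # m, default counting radius around the apex


@dataclass
class ParticleEnsemble:
    """Positions (N, 3) in metres relative to the tip apex, plus state."""

    positions: np.ndarray
    body: DielectricBody
    trapped: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.trapped is None:
            self.trapped = np.zeros(len(self.positions), dtype=bool)
        else:
            self.trapped = np.asarray(self.trapped, dtype=bool)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def radii(self) -> float:
        return self.body.radius

    def count_within(self, radius: float = TRAP_REGION_RADIUS) -> int:
        if not len(self):
            return 0
        r = np.linalg.norm(self.positions, axis=1)
        return int(np.count_nonzero(r <= radius))


@dataclass
class BrownianConfig:
    dt: float = 1.0e-5               # s
    n_steps: int = 10_000
    seed: int = 0
    box_half_width: float = 10.0e-6  # m
    contact_sticking: bool = True
    probe_velocity: float = 0.0      # m/s (used by run_translation)
    record_every: int = 100          # cadence for count_in_trap time series
    trap_region_radius: float = TRAP_REGION_RADIUS

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be > 0")
        if self.box_half_width <= self.trap_region_radius:
            raise ValueError("box must enclose the trap region")


@dataclass
class TrapSimResult:
    times: np.ndarray                      # s
    count_in_trap: np.ndarray              # per recorded time
    cluster_size_final: int
    dispersal_time: Optional[float] = None  # s
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.count_in_trap < 0):
            raise ValueError("counts must be >= 0")
        if not (0.0 <= self.retained_fraction <= 1.0):
            raise ValueError("retained_fraction must be in [0, 1]")


def diffusion_coefficient(medium: Medium, radius: float) -> float:
    """Stokes-Einstein D = kB T / (6 pi eta a)."""
    gamma = 6.0 * math.pi * medium.viscosity * radius
    return KB * medium.temperature / gamma


def _stable_dt(ensemble: ParticleEnsemble, medium: Medium, tip: TipFieldModel,
               drive: DepDrive, dt: float, config: "BrownianConfig") -> float:
    """Halve dt until the per-step drift at the trap-region edge is < a/5.

    The ``(r + r0)**-7`` force diverges toward contact, where no explicit
    step is stable; there the integrator instead clips drift to a/5 per
    step (deterministic capture, absorbed by contact sticking/reflection).
    The stability criterion is therefore enforced at the trap-region
    boundary, outside which trajectories must be accurate.
    """
    if not drive.enabled:
        return dt
    a = ensemble.body.radius
    gamma = 6.0 * math.pi * medium.viscosity * a
    pref = _force_prefactor(ensemble.body, medium, drive.frequency)
    if pref <= 0:
        return dt
    r_edge = config.trap_region_radius
    f_edge = pref * tip.g0 * drive.voltage_pp**2 / (r_edge + tip.tip_radius) ** 7
    while (f_edge / gamma) * dt > a / 5.0 and dt > 1e-12:
        dt /= 2.0
    return dt


def _radial_force(ensemble, medium, tip, drive, r):
    """Attractive radial force magnitude at centre distance r (vectorized)."""
    pref = _force_prefactor(ensemble.body, medium, drive.frequency)
    return pref * tip.g0 * drive.voltage_pp**2 / (r + tip.tip_radius) ** 7


def step_brownian(ensemble: ParticleEnsemble, medium: Medium, tip: TipFieldModel,
                  drive: DepDrive, config: BrownianConfig,
                  rng: np.random.Generator, dt: Optional[float] = None) -> ParticleEnsemble:
    """Advance the ensemble by one Euler-Maruyama step (in place).

    Reflecting boundaries at the box walls and at the probe contact sphere;
    with ``contact_sticking`` and the drive on, particles reaching contact
    are flagged trapped and pinned to the probe frame.
    """
    if not len(ensemble):
        return ensemble
    dt = config.dt if dt is None else dt
    a = ensemble.body.radius
    gamma = 6.0 * math.pi * medium.viscosity * a
    d_coef = KB * medium.temperature / gamma

    free = ~ensemble.trapped
    x = ensemble.positions

    if drive.enabled:
        r = np.linalg.norm(x[free], axis=1)
        r = np.maximum(r, 1e-12)
        f_mag = _radial_force(ensemble, medium, tip, drive, r)
        # move limit: near the apex the power-law force diverges; clip the
        # drift step to a/5 (capture there is deterministic regardless)
        step_len = np.minimum(f_mag / gamma * dt, a / 5.0)
        x[free] -= step_len[:, None] * (x[free] / r[:, None])

    noise = rng.standard_normal((int(np.count_nonzero(free)), 3))
    x[free] += math.sqrt(2.0 * d_coef * dt) * noise

    # reflect at box walls
    hw = config.box_half_width
    x[free] = np.where(x[free] > hw, 2 * hw - x[free], x[free])
    x[free] = np.where(x[free] < -hw, -2 * hw - x[free], x[free])

    # probe surface: particles cannot approach the apex closer than contact
    r = np.linalg.norm(x[free], axis=1)
    at_contact = r <= a
    if np.any(at_contact):
        idx = np.flatnonzero(free)[at_contact]
        if config.contact_sticking and drive.enabled:
            # pin at the contact sphere, pointing along the arrival direction
            u = x[idx]
            norms = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
            x[idx] = u / norms[:, None] * a
            ensemble.trapped[idx] = True
        else:
            u = x[idx]
            norms = np.maximum(np.linalg.norm(u, axis=1), 1e-12)
            # reflect off the contact sphere
            x[idx] = u / norms[:, None] * (2 * a - norms)[:, None]
    return ensemble


def run_trapping(ensemble: ParticleEnsemble, medium: Medium, tip: TipFieldModel,
                 drive: DepDrive, config: BrownianConfig) -> TrapSimResult:
    """Integrate capture dynamics and record trap occupancy over time."""
    rng = np.random.default_rng(config.seed)
    dt = _stable_dt(ensemble, medium, tip, drive, config.dt, config)
    n_sub = max(1, round(config.dt / dt))
    dt = config.dt / n_sub

    times, counts = [], []
    for i in range(config.n_steps):
        for _ in range(n_sub):
            step_brownian(ensemble, medium, tip, drive, config, rng, dt=dt)
        if i % config.record_every == 0 or i == config.n_steps - 1:
            times.append((i + 1) * config.dt)
            if config.contact_sticking and drive.enabled:
                counts.append(int(np.count_nonzero(ensemble.trapped)))
            else:
                counts.append(ensemble.count_within(config.trap_region_radius))
    return TrapSimResult(
        times=np.asarray(times), count_in_trap=np.asarray(counts),
        cluster_size_final=int(np.count_nonzero(ensemble.trapped)),
    )


def make_cluster(n: int, body: DielectricBody, rng: np.random.Generator,
                 cap_solid_angle_fraction: float = 0.25,
                 packing_fraction: float = 0.55) -> ParticleEnsemble:
    """A trapped cluster packed against the apex in a spherical cap.

    Bead k sits at centre distance ``a * max(1, ((k+1)/(phi*f))**(1/3))``
    with a random direction inside the cap; the first bead is at contact.
    """
    a = body.radius
    f = packing_fraction * cap_solid_angle_fraction
    pos = np.empty((n, 3))
    for k in range(n):
        d = a * max(1.0, ((k + 1) / f) ** (1.0 / 3.0)) if k else a
        # random direction in a polar cap of the given solid-angle fraction
        cos_max = 1.0 - 2.0 * cap_solid_angle_fraction
        c = rng.uniform(cos_max, 1.0)
        s = math.sqrt(max(0.0, 1.0 - c * c))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        pos[k] = d * np.array([s * math.cos(phi), s * math.sin(phi), c])
    ens = ParticleEnsemble(positions=pos, body=body)
    ens.trapped[:] = True
    return ens


def run_release(ensemble: ParticleEnsemble, medium: Medium, tip: TipFieldModel,
                config: BrownianConfig) -> TrapSimResult:
    """Pure-diffusion dispersal of a loaded cluster after drive-off.

    ``dispersal_time`` is the first time fewer than 10% of the initially
    trapped particles remain inside the trap region; ``None`` if the
    cluster never disperses within the simulated window.
    """
    n0 = len(ensemble)
    ensemble.trapped[:] = False
    off = DepDrive(voltage_pp=0.0, frequency=1.0e6, enabled=False)
    rng = np.random.default_rng(config.seed)
    threshold = 0.1 * n0

    dispersal_time = None
    times, counts = [], []
    for i in range(config.n_steps):
        step_brownian(ensemble, medium, tip, off, config, rng)
        c = ensemble.count_within(config.trap_region_radius)
        t = (i + 1) * config.dt
        if i % config.record_every == 0 or i == config.n_steps - 1:
            times.append(t)
            counts.append(c)
        if dispersal_time is None and c < threshold:
            dispersal_time = t
            break
    return TrapSimResult(
        times=np.asarray(times), count_in_trap=np.asarray(counts),
        cluster_size_final=0, dispersal_time=dispersal_time,
        retained_fraction=(counts[-1] / n0) if n0 else 0.0,
    )


def run_translation(ensemble: ParticleEnsemble, medium: Medium, tip: TipFieldModel,
                    drive: DepDrive, speed: float, distance: float) -> float:
    """Fraction of the cluster retained while the probe translates.

    Quasi-static drag balance: a trapped particle at centre distance d is
    shed when its Stokes drag ``6 pi eta a v`` exceeds the local DEP
    restoring force.  Exact for a single particle held at contact: the
    shedding-threshold speed is force/(6 pi eta a).
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    n = int(np.count_nonzero(ensemble.trapped))
    if n == 0:
        return 0.0
    if speed == 0.0:
        return 1.0
    a = ensemble.body.radius
    gamma = 6.0 * math.pi * medium.viscosity * a
    drag = gamma * speed
    r = np.linalg.norm(ensemble.positions[ensemble.trapped], axis=1)
    hold = _radial_force(ensemble, medium, tip, drive, r)
    kept = hold >= drag
    idx = np.flatnonzero(ensemble.trapped)[~kept]
    ensemble.trapped[idx] = False
    return float(np.count_nonzero(kept) / n)


def success_surface(medium: Medium, tip: TipFieldModel, body: DielectricBody,
                    voltages, dwells, n_rep: int = 10, seed: int = 0,
                    n_particles: int = 8, box_half_width: float = 4.0e-6,
                    retraction_speed: float = 1.0e-4, dt: float = 2.0e-5,
                    init_positions=None) -> np.ndarray:
    """Monte-Carlo biopsy success probability over a voltage x dwell grid.

    Success = at least one particle trapped during the dwell and retained
    through a standard retraction at ``retraction_speed``.  Returns an
    array of shape (len(voltages), len(dwells)).
    """
    voltages = list(voltages)
    dwells = list(dwells)
    if not voltages or not dwells:
        raise ValueError("voltages and dwells must be nonempty")
    out = np.zeros((len(voltages), len(dwells)))
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=n_rep)
    for i, v in enumerate(voltages):
        for j, dwell in enumerate(dwells):
            n_steps = max(1, int(round(dwell / dt)))
            wins = 0
            for s in rep_seeds:
                rng = np.random.default_rng([int(s), i, j])
                if init_positions is not None:
                    pos = np.array(init_positions, dtype=float, copy=True)
                else:
                    pos = rng.uniform(-box_half_width, box_half_width,
                                      size=(n_particles, 3))
                ens = ParticleEnsemble(positions=pos, body=body)
                drive = DepDrive(voltage_pp=v, frequency=tip.reference_drive.frequency,
                                 enabled=v > 0)
                cfg = BrownianConfig(dt=dt, n_steps=n_steps, seed=int(s),
                                     box_half_width=box_half_width,
                                     record_every=max(1, n_steps // 4))
                res = run_trapping(ens, medium, tip, drive, cfg)
                if res.cluster_size_final > 0 and v > 0:
                    run_translation(ens, medium, tip, drive, retraction_speed,
                                    distance=10e-6)
                    if np.count_nonzero(ens.trapped) > 0:
                        wins += 1
            out[i, j] = wins / n_rep
    return out
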