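"""3D agent-based fire-diffuse-fire (FDF) simulator of potassium wavefronts.

Cells packed in a spherical biofilm release potassium into the surrounding
fluid when the local extracellular K+ concentration crosses a firing
threshold; the ion diffuses and is cleared, relaying the excitation outward
as a saltatory centrifugal wavefront. After the wave covers the biofilm the
fluorescence proxy collapses from the periphery back to the core
(centripetal phase), the system goes quiescent, and — mimicking habituation
to the sustained light stress — cells re-brighten to a persistent plateau.

Numerics: the extracellular field c(x, t) obeys dc/dt = D lap(c) - k c on a
regular cubic grid (explicit 7-point finite differences, CFL condition
D dt / dx^2 <= 1/6 enforced), with an absorbing boundary emulating the
flow-fed fluid environment placed at three biofilm radii from the center.
Agents couple to the grid by trilinear deposition and sampling. Each cell
carries a ThT-like fluorescence proxy that integrates the local
concentration once the cell has fired and decays first-order, so the bright
region follows the wave and then collapses with the clearing field.

All randomness (lattice jitter) flows from a single integer seed; identical
parameters and seed give bit-identical frame sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .traces import ThTTrace

__all__ = [
    "FDFParams",
    "CellAgent",
    "BiofilmGeometry",
    "PotassiumField",
    "SimFrame",
    "CellState",
    "build_spherical_biofilm",
    "diffuse_step",
    "fire_update",
    "run_simulation",
    "find_critical_radius",
    "global_tht_trace",
]


class CellState:
    """Agent firing-cycle states (quiescent -> firing -> refractory -> ...)."""

    QUIESCENT = 0
    FIRING = 1
    REFRACTORY = 2
    HABITUATED = 3

    NAMES = {0: "quiescent", 1: "firing", 2: "refractory", 3: "habituated"}


@dataclass(frozen=True)
class FDFParams:
    """Canonical parameter set of the fire-diffuse-fire model.

    The defaults are the repository's pinned configuration, calibrated once
    (scripts/tune_fdf.py) so that ensembles of default runs reproduce the
    model's three headline outputs: centrifugal exponent gamma ~ 1.21,
    centripetal exponent gamma ~ 2.26, and critical radius ~ 6.2 um.

    Units: lengths um, time min, concentration in threshold units
    (c_thresh = 1 defines the scale), release in concentration * um^3.
    """

    D: float = 2.0  # um^2/min, effective extracellular K+ diffusivity
    k_decay: float = 1.2  # 1/min, clearance in the flow-fed fluid
    c_thresh: float = 1.0  # firing threshold concentration (inclusive)
    sigma_release: float = 35.0  # conc * um^3 released per firing event
    t_fire: float = 2.0  # min, release duration
    t_refract: float = 18.0  # min, refractory period
    k_uptake: float = 2.6  # um^3/min, K+ re-uptake by recovering cells
    #: clearance inside the biofilm relative to the flow-fed fluid outside;
    #: the crowded interior is shielded from the flow (0 = no interior
    #: clearance beyond cellular re-uptake)
    interior_decay_fraction: float = 0.0
    tht_gain: float = 1.0  # 1/min, fluorescence-proxy gain on local c
    tht_decay: float = 0.3  # 1/min, per-cell proxy decay
    habituation_delay: float = 20.0  # min, quiescence before plateau refiring
    plateau_level: float = 0.6  # habituated proxy plateau (arb. units)
    tau_plateau: float = 10.0  # min, rise time of the habituated plateau
    trigger_boost: float = 1.0  # release multiplier for the core trigger
    spacing: float = 1.5  # um, nearest-neighbour cell spacing
    jitter: float = 0.15  # lattice jitter fraction (< 0.5)
    grid_dx: float = 1.5  # um, diffusion grid spacing
    dt: float = 0.05  # min, time step
    domain_factor: float = 3.0  # absorbing boundary at >= this many radii
    max_agents: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D", "c_thresh", "sigma_release", "t_fire", "t_refract",
                     "grid_dx", "dt", "spacing", "tht_decay", "tau_plateau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("k_decay", "k_uptake", "tht_gain", "habituation_delay",
                     "plateau_level", "trigger_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.jitter < 0.5:
            raise ValueError("jitter must lie in [0, 0.5)")
        if not 0 <= self.interior_decay_fraction <= 1:
            raise ValueError("interior_decay_fraction must lie in [0, 1]")
        if self.grid_dx > self.spacing + 1e-12:
            raise ValueError("grid_dx must not exceed the cell spacing")
        if self.domain_factor < 3.0:
            raise ValueError("absorbing boundary must sit at >= 3 biofilm radii")
        cfl = self.D * self.dt / self.grid_dx**2
        if cfl > 1.0 / 6.0 + 1e-12:
            raise ValueError(
                f"diffusion stability violated: D*dt/dx^2 = {cfl:.4g} > 1/6; "
                f"use dt <= {self.grid_dx**2 / (6 * self.D):.4g} min"
            )


@dataclass
class CellAgent:
    """Read-out record for a single agent (the simulator is vectorized)."""

    position: tuple[float, float, float]  # um
    state: str  # quiescent | firing | refractory | habituated
    state_clock: float  # min since last transition
    tht: float  # fluorescence proxy, >= 0
    fired_count: int


@dataclass
class BiofilmGeometry:
    """Spherical biofilm: agent positions plus their (mutable) firing state.

    ``positions`` is an (N, 3) array in um about the origin. State arrays
    are advanced in place by :func:`fire_update`.
    """

    positions: np.ndarray
    radius: float  # um
    spacing: float  # um
    bounding_box: float  # um, half-width of the fluid domain
    lattice_positions: np.ndarray = field(default=None)  # pre-jitter sites
    states: np.ndarray = field(default=None)  # int per CellState
    clocks: np.ndarray = field(default=None)  # min in current state
    tht: np.ndarray = field(default=None)
    fired_count: np.ndarray = field(default=None)
    fire_time: np.ndarray = field(default=None)  # min of first firing (nan if never)
    release_scale: np.ndarray = field(default=None)  # per-cell release multiplier
    released_mass: float = 0.0  # cumulative K+ released (conc * um^3)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = self.positions.shape[0]
        if self.lattice_positions is None:
            self.lattice_positions = self.positions.copy()
        if self.states is None:
            self.states = np.full(n, CellState.QUIESCENT, dtype=np.int8)
        if self.clocks is None:
            self.clocks = np.zeros(n)
        if self.tht is None:
            self.tht = np.zeros(n)
        if self.fired_count is None:
            self.fired_count = np.zeros(n, dtype=np.int64)
        if self.fire_time is None:
            self.fire_time = np.full(n, np.nan)
        if self.release_scale is None:
            self.release_scale = np.ones(n)

    @property
    def n_cells(self) -> int:
        return int(self.positions.shape[0])

    @property
    def radial_distance(self) -> np.ndarray:
        """Distance of every cell from the biofilm center (um)."""
        return np.linalg.norm(self.positions, axis=1)

    @property
    def cells(self) -> list[CellAgent]:
        """Materialize per-cell records (for inspection; the arrays are
        authoritative)."""
        return [
            CellAgent(
                position=tuple(self.positions[i]),
                state=CellState.NAMES[int(self.states[i])],
                state_clock=float(self.clocks[i]),
                tht=float(self.tht[i]),
                fired_count=int(self.fired_count[i]),
            )
            for i in range(self.n_cells)
        ]


@dataclass
class PotassiumField:
    """Extracellular K+ concentration on a regular cubic grid.

    ``grid[i, j, k]`` is the concentration at position
    ``origin + (i, j, k) * dx`` (voxel centers). The boundary condition is
    absorbing (concentration clamped to zero on the outermost voxel layer,
    emulating a flow-fed far field) or reflective (zero flux, used by
    mass-balance tests).
    """

    grid: np.ndarray
    dx: float  # um
    origin: np.ndarray  # um, position of grid[0,0,0]
    boundary: str = "absorbing"
    #: optional per-voxel multiplier on the bulk clearance rate; models the
    #: flow-fed fluid (full clearance) versus the shielded biofilm interior
    decay_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("field grid must be 3-D")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.boundary not in ("absorbing", "reflective"):
            raise ValueError("boundary must be 'absorbing' or 'reflective'")
        if self.decay_mask is not None and self.decay_mask.shape != self.grid.shape:
            raise ValueError("decay_mask must match the grid shape")

    @classmethod
    def for_domain(cls, half_width: float, dx: float,
                   boundary: str = "absorbing") -> "PotassiumField":
        """Empty field on a cube [-half_width, half_width]^3 about the origin."""
        n = 2 * int(math.floor(half_width / dx)) + 1
        origin = -dx * (n - 1) / 2.0 * np.ones(3)
        return cls(grid=np.zeros((n, n, n)), dx=dx, origin=origin,
                   boundary=boundary)

    @property
    def voxel_volume(self) -> float:
        return self.dx**3

    def total_mass(self) -> float:
        """Total dissolved K+ (concentration * volume units)."""
        return float(self.grid.sum() * self.voxel_volume)

    def _grid_coords(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = (np.atleast_2d(positions) - self.origin) / self.dx
        i0 = np.floor(g).astype(int)
        frac = g - i0
        shape = np.array(self.grid.shape)
        if np.any(i0 < 0) or np.any(i0 + 1 >= shape):
            bad = np.where((i0 < 0).any(axis=1) | (i0 + 1 >= shape).any(axis=1))[0]
            raise ValueError(
                f"positions outside the field domain: indices {bad.tolist()}"
            )
        return i0, frac

    def sample(self, positions: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the field at agent positions."""
        i0, f = self._grid_coords(positions)
        c = np.zeros(i0.shape[0])
        for dx_ in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[:, 0] if dx_ else 1 - f[:, 0])
                        * (f[:, 1] if dy else 1 - f[:, 1])
                        * (f[:, 2] if dz else 1 - f[:, 2])
                    )
                    c += w * self.grid[i0[:, 0] + dx_, i0[:, 1] + dy, i0[:, 2] + dz]
        return c

    def deposit(self, positions: np.ndarray, masses: np.ndarray) -> None:
        """Trilinearly deposit point masses (conc * um^3) into the grid."""
        i0, f = self._grid_coords(positions)
        conc = np.asarray(masses, dtype=float) / self.voxel_volume
        flat = self.grid.ravel()
        sx, sy, sz = self.grid.shape
        for dx_ in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[:, 0] if dx_ else 1 - f[:, 0])
                        * (f[:, 1] if dy else 1 - f[:, 1])
                        * (f[:, 2] if dz else 1 - f[:, 2])
                    )
                    idx = (
                        (i0[:, 0] + dx_) * sy * sz
                        + (i0[:, 1] + dy) * sz
                        + (i0[:, 2] + dz)
                    )
                    np.add.at(flat, idx, w * conc)


@dataclass(frozen=True)
class SimFrame:
    """Snapshot of the simulation at one recorded time."""

    t: float  # min
    states: np.ndarray  # per-cell CellState codes
    tht: np.ndarray  # per-cell fluorescence proxy
    global_tht: float  # mean per-cell proxy
    released_mass: float  # cumulative K+ released up to t
    field_mass: float  # K+ currently dissolved in the field
    field_snapshot: np.ndarray | None = None


def build_spherical_biofilm(
    radius: float,
    spacing: float,
    jitter: float = 0.15,
    seed: int = 0,
    max_agents: int = 100_000,
    domain_factor: float = 3.0,
) -> BiofilmGeometry:
    """Place cells on a jittered cubic lattice clipped to a sphere.

    Lattice membership is decided on the unjittered lattice, so the cell
    count is deterministic for given (radius, spacing); jittered positions
    are clamped back inside the sphere. The fluid bounding box extends
    ``domain_factor`` biofilm radii from the center (at least a few grid
    cells beyond the biofilm for tiny radii).

    Raises
    ------
    ValueError
        If the requested geometry would exceed ``max_agents`` (the message
        carries the count), or for invalid radius/spacing/jitter.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must lie in [0, 0.5)")
    kmax = int(math.floor(radius / spacing))
    ax = np.arange(-kmax, kmax + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    lattice = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]) * spacing
    inside = np.linalg.norm(lattice, axis=1) <= radius + 1e-9
    pts = lattice[inside]
    if pts.shape[0] == 0:
        # only the origin point can fit
        pts = np.zeros((1, 3))
    if pts.shape[0] > max_agents:
        raise ValueError(
            f"geometry would contain {pts.shape[0]} agents, exceeding the "
            f"configured maximum of {max_agents}"
        )
    rng = np.random.default_rng(seed)
    lattice_pts = pts.copy()
    if jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape) * spacing
        norms = np.linalg.norm(pts, axis=1)
        over = norms > radius
        if np.any(over) and radius > 0:
            pts[over] *= (radius / norms[over])[:, None]
    half_width = max(domain_factor * radius, radius + 4.0 * spacing)
    return BiofilmGeometry(
        positions=pts, radius=radius, spacing=spacing,
        bounding_box=half_width, lattice_positions=lattice_pts,
    )


def _laplacian(grid: np.ndarray, dx: float, boundary: str) -> np.ndarray:
    """7-point Laplacian; outside voxels are 0 (absorbing) or mirrored
    (reflective)."""
    mode = "constant" if boundary == "absorbing" else "edge"
    padded = np.pad(grid, 1, mode=mode)
    lap = (
        padded[2:, 1:-1, 1:-1] + padded[:-2, 1:-1, 1:-1]
        + padded[1:-1, 2:, 1:-1] + padded[1:-1, :-2, 1:-1]
        + padded[1:-1, 1:-1, 2:] + padded[1:-1, 1:-1, :-2]
        - 6.0 * grid
    ) / dx**2
    return lap


def diffuse_step(
    field: PotassiumField, D: float, k_decay: float, dt: float
) -> PotassiumField:
    """One explicit finite-difference step of dc/dt = D lap(c) - k_decay c.

    Non-negativity is preserved under the CFL condition
    D dt / dx^2 <= 1/6 (and k_decay dt <= 1), which is checked before any
    stepping. Returns a new field; the input is not modified.
    """
    if D < 0 or k_decay < 0 or dt <= 0:
        raise ValueError("D, k_decay must be >= 0 and dt > 0")
    cfl = D * dt / field.dx**2
    if cfl > 1.0 / 6.0 + 1e-12:
        raise ValueError(
            f"diffusion stability violated: D*dt/dx^2 = {cfl:.4g} > 1/6"
        )
    if k_decay * dt > 1.0:
        raise ValueError("k_decay * dt must not exceed 1")
    lap = _laplacian(field.grid, field.dx, field.boundary)
    decay = k_decay * field.grid
    if field.decay_mask is not None:
        decay = decay * field.decay_mask
    new_grid = field.grid + dt * (D * lap - decay)
    if field.boundary == "absorbing":
        new_grid[0, :, :] = new_grid[-1, :, :] = 0.0
        new_grid[:, 0, :] = new_grid[:, -1, :] = 0.0
        new_grid[:, :, 0] = new_grid[:, :, -1] = 0.0
    return replace(field, grid=new_grid)


def fire_update(
    geometry: BiofilmGeometry,
    field: PotassiumField,
    params: FDFParams,
    t: float,
) -> tuple[BiofilmGeometry, PotassiumField]:
    """Advance the agent state machine by one step params.dt at time t.

    Pure threshold state machine (no randomness): a quiescent cell whose
    local concentration reaches c_thresh (inclusive) starts firing and
    deposits sigma_release (times its release_scale) spread uniformly over
    t_fire; a firing cell past t_fire turns refractory; a refractory cell
    past t_refract returns to quiescence, or — if the global clock has
    passed habituation_delay — habituates and rises to the persistent
    plateau. The fluorescence proxy of a fired cell integrates the local
    concentration with gain tht_gain and decays at tht_decay.

    The geometry's state arrays and the field grid are updated in place;
    the (geometry, field) pair is returned for chaining.
    """
    dt = params.dt
    c_local = field.sample(geometry.positions)
    states = geometry.states

    # quiescent -> firing (threshold inclusive)
    ignite = (states == CellState.QUIESCENT) & (c_local >= params.c_thresh)
    if np.any(ignite):
        states[ignite] = CellState.FIRING
        geometry.clocks[ignite] = 0.0
        geometry.fired_count[ignite] += 1
        first = ignite & np.isnan(geometry.fire_time)
        geometry.fire_time[first] = t

    # firing cells release K+ spread uniformly over t_fire
    firing = states == CellState.FIRING
    if np.any(firing):
        frac = np.minimum(dt, params.t_fire - geometry.clocks[firing])
        frac = np.clip(frac, 0.0, None) / params.t_fire
        masses = params.sigma_release * geometry.release_scale[firing] * frac
        field.deposit(geometry.positions[firing], masses)
        geometry.released_mass += float(np.sum(masses))

    # recovering cells pump K+ back in (restoring their ion gradient): a
    # sink proportional to the local concentration, so the growing fired
    # region increasingly saps the wave's substrate
    if params.k_uptake > 0:
        recovering = (states == CellState.REFRACTORY) | (
            states == CellState.HABITUATED
        )
        if np.any(recovering):
            uptake = (
                params.k_uptake * c_local[recovering] * dt
            )  # mass removed per cell
            field.deposit(geometry.positions[recovering], -uptake)
            np.clip(field.grid, 0.0, None, out=field.grid)

    # fluorescence proxy: fired cells integrate local c and decay;
    # habituated cells relax to the persistent plateau instead
    hab = states == CellState.HABITUATED
    fired = (firing | (states == CellState.REFRACTORY)) & ~hab
    drive = np.where(fired, params.tht_gain * c_local, 0.0)
    not_hab = ~hab
    geometry.tht[not_hab] += dt * (
        drive[not_hab] - params.tht_decay * geometry.tht[not_hab]
    )
    if np.any(hab):
        geometry.tht[hab] += dt * (
            params.plateau_level - geometry.tht[hab]
        ) / params.tau_plateau
    np.clip(geometry.tht, 0.0, None, out=geometry.tht)

    # clocks and state transitions
    geometry.clocks[states != CellState.QUIESCENT] += dt
    done_firing = firing & (geometry.clocks >= params.t_fire)
    states[done_firing] = CellState.REFRACTORY
    geometry.clocks[done_firing] = 0.0
    done_refract = (states == CellState.REFRACTORY) & (
        geometry.clocks >= params.t_refract
    )
    if np.any(done_refract):
        if t > params.habituation_delay:
            states[done_refract] = CellState.HABITUATED
        else:
            states[done_refract] = CellState.QUIESCENT
        geometry.clocks[done_refract] = 0.0
    return geometry, field


def run_simulation(
    params: FDFParams,
    geometry: BiofilmGeometry,
    duration: float,
    trigger: np.ndarray | Sequence[int] | None = None,
    frame_dt: float = 0.1,
    record_field: bool = False,
) -> list[SimFrame]:
    """Run the FDF model and return frames at a fixed cadence.

    ``trigger`` selects the cells forced to fire at t = 0 (indices or a
    boolean mask); by default, all cells within one lattice spacing of the
    origin. Trigger cells release ``trigger_boost`` times the standard
    amount, representing the strong initial excitation at the biofilm core.
    Fully reproducible: geometry seed plus parameters determine every frame.

    Raises
    ------
    ValueError
        For an empty trigger region or stability violations.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if trigger is None:
        # select by nominal (unjittered) lattice sites so the trigger region
        # is the same deterministic 7-cell core for every jitter realization
        lattice_r = np.linalg.norm(
            np.atleast_2d(geometry.lattice_positions), axis=1
        )
        trigger_mask = lattice_r <= geometry.spacing + 1e-9
    else:
        trigger = np.asarray(trigger)
        if trigger.dtype == bool:
            trigger_mask = trigger
        else:
            trigger_mask = np.zeros(geometry.n_cells, dtype=bool)
            trigger_mask[trigger] = True
    if not np.any(trigger_mask):
        raise ValueError("trigger region is empty: no cell within reach")

    field = PotassiumField.for_domain(
        half_width=geometry.bounding_box, dx=params.grid_dx
    )
    if params.interior_decay_fraction < 1.0 and geometry.radius > 0:
        n = field.grid.shape[0]
        ax = field.origin[0] + params.grid_dx * np.arange(n)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = X**2 + Y**2 + Z**2 <= geometry.radius**2
        mask = np.ones_like(field.grid)
        mask[inside] = params.interior_decay_fraction
        field.decay_mask = mask
    geometry.release_scale[trigger_mask] = params.trigger_boost
    geometry.states[trigger_mask] = CellState.FIRING
    geometry.clocks[trigger_mask] = 0.0
    geometry.fired_count[trigger_mask] += 1
    geometry.fire_time[trigger_mask] = 0.0

    n_steps = int(round(duration / params.dt))
    record_every = max(1, int(round(frame_dt / params.dt)))
    frames: list[SimFrame] = []

    def snapshot(t: float) -> SimFrame:
        return SimFrame(
            t=t,
            states=geometry.states.copy(),
            tht=geometry.tht.copy(),
            global_tht=float(geometry.tht.mean()),
            released_mass=geometry.released_mass,
            field_mass=field.total_mass(),
            field_snapshot=field.grid.copy() if record_field else None,
        )

    frames.append(snapshot(0.0))
    for step in range(n_steps):
        t = step * params.dt
        field = diffuse_step(field, params.D, params.k_decay, params.dt)
        geometry, field = fire_update(geometry, field, params, t)
        if (step + 1) % record_every == 0 or step == n_steps - 1:
            frames.append(snapshot((step + 1) * params.dt))
    return frames


def propagation_success(
    params: FDFParams,
    radius: float,
    seed: int,
    duration: float | None = None,
    outer_fraction_required: float = 0.9,
) -> bool:
    """Did a core-triggered wave reach the biofilm periphery?

    Success means at least ``outer_fraction_required`` of the outer-shell
    cells (within one spacing of the surface) fired during the run.
    """
    geometry = build_spherical_biofilm(
        radius=radius, spacing=params.spacing, jitter=params.jitter,
        seed=seed, max_agents=params.max_agents,
        domain_factor=params.domain_factor,
    )
    if duration is None:
        # generous window: slow marginal waves advance at ~1 um/min
        duration = max(12.0, 2.5 * radius)
    run_simulation(params, geometry, duration=duration, frame_dt=duration)
    r = geometry.radial_distance
    outer = r >= radius - params.spacing
    if not np.any(outer):
        outer = r >= r.max() - 1e-9
    frac = float(np.mean(geometry.fired_count[outer] > 0))
    return frac >= outer_fraction_required


def find_critical_radius(
    params: FDFParams,
    radius_lo: float,
    radius_hi: float,
    n_seeds: int = 10,
    tol: float = 0.25,
    duration: float | None = None,
    seeds: Sequence[int] | None = None,
) -> tuple[float, float]:
    """Critical biofilm radius for wavefront propagation, by seeded bisection.

    For each seed (``seeds`` if given, else 0..n_seeds-1) the
    propagation-success indicator (wavefront reaches the periphery: >= 90%
    of outer-shell cells fire) is bisected between a failing ``radius_lo``
    and a succeeding ``radius_hi``; the mean and sample SD of the per-seed
    thresholds are returned (um).

    Raises
    ------
    ValueError
        If the bracket is violated for some seed (propagation succeeds at
        radius_lo or fails at radius_hi); the message instructs widening
        the bounds.
    """
    if not radius_lo < radius_hi:
        raise ValueError("radius_lo must be smaller than radius_hi")
    if seeds is None:
        seeds = range(n_seeds)
    if len(list(seeds)) < 1:
        raise ValueError("at least one seed is required")
    estimates = []
    for seed in seeds:
        lo, hi = radius_lo, radius_hi
        if propagation_success(params, lo, seed, duration):
            raise ValueError(
                f"bracketing violated for seed {seed}: propagation succeeds "
                f"at radius_lo={lo}; widen the bracket downward"
            )
        if not propagation_success(params, hi, seed, duration):
            raise ValueError(
                f"bracketing violated for seed {seed}: propagation fails at "
                f"radius_hi={hi}; widen the bracket upward"
            )
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if propagation_success(params, mid, seed, duration):
                hi = mid
            else:
                lo = mid
        estimates.append(0.5 * (lo + hi))
    estimates = np.asarray(estimates)
    sd = float(estimates.std(ddof=1)) if len(estimates) > 1 else 0.0
    return float(estimates.mean()), sd


def global_tht_trace(frames: Sequence[SimFrame]) -> ThTTrace:
    """Biofilm-wide fluorescence proxy: mean per-cell tht per frame."""
    if len(frames) == 0:
        raise ValueError("empty frame list")
    times = np.array([f.t for f in frames])
    intensity = np.array([f.global_tht for f in frames])
    return ThTTrace(times=times, intensity=intensity, label="fdf-global")
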