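"""Two-channel Hodgkin-Huxley model of E. coli membrane potential under
blue-light stress.

The globally averaged membrane potential V obeys

    C_m dV/dt = -[ g_Q m_Q h_Q (V - E_Q) + g_K n_K^p (V - E_K)
                   + g_L (V - E_L) ]

with two voltage-gated cation channels — Q, the fast "stress registration"
channel (minimally the product of the mechanosensitive channels
MscK x MscL x MscS), and Kch, the voltage-gated potassium channel — plus a
leak. Each gate relaxes first-order to its steady state,
dx/dt = (x_inf - x)/tau_x, and a light-driven reactive-oxygen-species (ROS)
stress variable accumulates as dS/dt = alpha_ROS * I(t) - delta_ROS * S.

Gating couplings (the model's mechanistic choices):

* Q activation ``m_Q`` is gated directly by irradiance with Michaelis form
  I/(I + I_half): light opens Q fast, producing the first hyperpolarization.
  The first event is deliberately ROS-independent, because scavenging ROS
  (catalase) leaves the first peak intact.
* Q inactivation ``h_Q`` is voltage-windowed: the gate inactivates only at
  intermediate voltages (the band visited when Kch pulls the cell back up
  from the deep Q plateau). Without Kch the cell never enters the window, so
  the Delta-kch mutant stays hyperpolarized — one peak followed by a plateau
  with no repolarization. Recovery from inactivation is effectively frozen
  until ROS accumulates; crossing the stress latch re-primes h_Q
  (habituation), producing the second, persistent hyperpolarization.
* Kch activation ``n_K`` is hyperpolarization-activated (it opens during the
  first event and repolarizes the cell toward E_K and then, by deactivating,
  lets the leak restore rest) and is suppressed once the stress latch is
  crossed, so the habituated plateau is Q-dominated and deep.

The printed working irradiance threshold for the second peak,
15.99 uW/mm^2, enters through the stress latch level: at the default
ROS production/clearance rates the latch is crossed ~35 min into a
constant-threshold exposure, so the second peak occurs within a 60-min
protocol exactly for irradiances at or above threshold.

ThT fluorescence is a Nernstian readout of V (see :func:`tht_readout`).
Units: time min, voltage mV, irradiance uW/mm^2; conductances and
capacitance in arbitrary-but-consistent membrane units (mS/cm^2, uF/cm^2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .traces import ThTTrace

__all__ = [
    "GateSigmoid",
    "HHParams",
    "MembraneState",
    "MembraneTrajectory",
    "StimulusProgram",
    "gate_steady_state",
    "simulate_membrane",
    "tht_readout",
    "irradiance_from_power",
    "make_variant",
    "VARIANTS",
]

THERMAL_VOLTAGE_MV = 26.0  # k_B T / e at room temperature, mV


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically safe logistic 1/(1+exp(-x))."""
    x = np.clip(x, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GateSigmoid:
    """Parameters of a logistic gating steady state sigma((V - v_half)/slope).

    A positive slope opens the gate with depolarization, a negative slope
    with hyperpolarization.
    """

    v_half: float  # mV
    slope: float  # mV, nonzero

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("gate sigmoid slope must be nonzero")


def gate_steady_state(V: float | np.ndarray, gate: GateSigmoid) -> float | np.ndarray:
    """Steady-state activation of a logistic gate at membrane potential V.

    Returns a value in (0, 1), monotone in V for fixed parameters
    (increasing for positive slope, decreasing for negative).

    Raises
    ------
    ValueError
        If V is non-finite.
    """
    V_arr = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V_arr)):
        raise ValueError("membrane potential must be finite")
    out = _logistic((V_arr - gate.v_half) / gate.slope)
    if np.isscalar(V) or V_arr.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class HHParams:
    """Parameters of the two-channel conductance model.

    The defaults are the package's canonical wildtype set, pinned so that a
    constant exposure at the working irradiance (15.99 uW/mm^2) reproduces
    the qualitative regime structure of the observed dynamics: first
    hyperpolarization peak near 3 min, quiescence from roughly 10 to 35 min,
    habituated plateau established by ~45 min and persisting.
    """

    # membrane
    C_m: float = 1.0  # uF/cm^2
    g_Q: float = 1.0  # mS/cm^2, maximal Q conductance
    g_K: float = 1.6  # mS/cm^2, maximal Kch conductance
    g_L: float = 0.3  # mS/cm^2, leak
    E_Q: float = -150.0  # mV
    E_K: float = -85.0  # mV (below rest: K+ efflux hyperpolarizes)
    E_L: float = -60.0  # mV, resting potential
    p_K: int = 1  # Kch gate cooperativity exponent

    # time constants (min)
    tau_act_Q: float = 0.3  # Q activation (light gate m_Q)
    tau_inact_Q: float = 2.0  # Q inactivation (h_Q falling)
    tau_act_K: float = 1.5  # Kch activation (n_K rising)
    tau_deact_K: float = 0.4  # Kch deactivation (n_K falling)
    tau_recover_Q: float = 500.0  # h_Q recovery without ROS (effectively frozen)
    tau_habituate: float = 3.0  # h_Q recovery once the ROS latch is crossed

    # gating sigmoids
    I_half_Q: float = 8.0  # uW/mm^2, Michaelis constant of light-gated m_Q
    h_window_low: GateSigmoid = field(
        default_factory=lambda: GateSigmoid(v_half=-100.0, slope=3.0)
    )
    h_window_high: GateSigmoid = field(
        default_factory=lambda: GateSigmoid(v_half=-75.0, slope=-3.0)
    )
    n_gate: GateSigmoid = field(
        default_factory=lambda: GateSigmoid(v_half=-95.0, slope=-7.0)
    )

    # ROS stress
    alpha_ROS: float = 0.1  # stress-units * mm^2 / uW / min
    delta_ROS: float = 0.05  # 1/min
    irradiance: float = 15.99  # uW/mm^2, applied light power density
    irradiance_threshold: float = 15.99  # uW/mm^2, second-peak threshold
    t_latch: float = 35.0  # min, latch-crossing time at threshold irradiance
    stress_half: float | None = None  # latch level; derived if None
    stress_sharpness: float = 20.0  # latch steepness, S_half / k_S

    def __post_init__(self) -> None:
        for name in ("C_m", "g_L", "tau_act_Q", "tau_inact_Q", "tau_act_K",
                     "tau_deact_K", "tau_recover_Q", "tau_habituate",
                     "I_half_Q", "delta_ROS"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("g_Q", "g_K", "alpha_ROS", "irradiance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.tau_act_Q < self.tau_act_K:
            raise ValueError(
                "tau_act_Q must be < tau_act_K (Q activates faster than Kch)"
            )
        if not self.tau_inact_Q > self.tau_deact_K:
            raise ValueError(
                "tau_inact_Q must be > tau_deact_K "
                "(Q inactivates slower than Kch deactivates)"
            )
        if not self.E_K < self.E_L:
            raise ValueError(
                "E_K must lie below the resting potential E_L "
                "(potassium efflux hyperpolarizes)"
            )
        if self.stress_half is None:
            # Latch level such that a constant exposure at the threshold
            # irradiance crosses it t_latch minutes in. Pinned at
            # construction so variant edits (e.g. alpha_ROS = 0) keep it.
            s_star = self.alpha_ROS * self.irradiance_threshold / self.delta_ROS
            level = s_star * (1.0 - math.exp(-self.delta_ROS * self.t_latch))
            object.__setattr__(self, "stress_half", level)

    # -- gating steady states -------------------------------------------

    def stress_gate(self, S: float) -> float:
        """sigma_S(S): smooth ROS latch in [0, 1)."""
        if self.stress_half is None or self.stress_half <= 0:
            return 0.0
        k = self.stress_half / self.stress_sharpness
        return float(_logistic((S - self.stress_half) / k))

    def m_inf(self, irradiance: float) -> float:
        """Light-gated Q activation steady state."""
        return irradiance / (irradiance + self.I_half_Q)

    def h_inf(self, V: float, S: float) -> float:
        """Q inactivation steady state: voltage window, re-primed by ROS."""
        in_window = gate_steady_state(V, self.h_window_low) * gate_steady_state(
            V, self.h_window_high
        )
        return max(1.0 - in_window, self.stress_gate(S))

    def n_inf(self, V: float, S: float) -> float:
        """Kch activation: hyperpolarization-activated, ROS-suppressed."""
        return gate_steady_state(V, self.n_gate) * (1.0 - self.stress_gate(S))

    def fastest_timescale(self) -> float:
        """Smallest time constant in the system (min), for dt validation."""
        g_total = self.g_Q + self.g_K + self.g_L
        return min(
            self.tau_act_Q,
            self.tau_deact_K,
            self.tau_inact_Q,
            self.tau_act_K,
            self.C_m / g_total,
        )


@dataclass(frozen=True)
class MembraneState:
    """Instantaneous state of the membrane model."""

    t: float  # min
    V: float  # mV
    m_Q: float  # Q activation gate in [0, 1]
    h_Q: float  # Q inactivation gate in [0, 1]
    n_K: float  # Kch activation gate in [0, 1]
    S: float  # accumulated ROS stress, >= 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.V):
            raise ValueError("membrane potential must be finite")
        for gate in ("m_Q", "h_Q", "n_K"):
            x = getattr(self, gate)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gate {gate}={x} outside [0, 1]")
        if self.S < 0:
            raise ValueError("stress S must be non-negative")

    @classmethod
    def resting(cls, params: HHParams) -> "MembraneState":
        """Dark-adapted rest: V at E_L, Q primed, Kch closed, no stress."""
        V0 = params.E_L
        return cls(
            t=0.0,
            V=V0,
            m_Q=0.0,
            h_Q=params.h_inf(V0, 0.0),
            n_K=params.n_inf(V0, 0.0),
            S=0.0,
        )


@dataclass(frozen=True)
class StimulusProgram:
    """Blue-light stimulation schedule.

    ``schedule`` is an ordered list of (start_min, stop_min, irradiance)
    intervals; outside every interval the irradiance is zero. Intervals must
    be non-overlapping and lie within [0, total_duration].
    """

    schedule: tuple[tuple[float, float, float], ...]
    total_duration: float  # min

    def __post_init__(self) -> None:
        sched = tuple(
            (float(a), float(b), float(i)) for a, b, i in self.schedule
        )
        object.__setattr__(self, "schedule", sched)
        if self.total_duration < 0:
            raise ValueError("total_duration must be non-negative")
        prev_stop = -math.inf
        for start, stop, irr in sched:
            if not 0 <= start < stop <= self.total_duration:
                raise ValueError(
                    f"interval ({start}, {stop}) outside [0, {self.total_duration}]"
                )
            if start < prev_stop:
                raise ValueError("stimulus intervals must be non-overlapping")
            if irr < 0:
                raise ValueError("irradiance must be non-negative")
            prev_stop = stop

    @classmethod
    def constant(cls, irradiance: float, duration: float) -> "StimulusProgram":
        """Continuous exposure at a fixed irradiance for ``duration`` min."""
        if duration <= 0:
            return cls(schedule=(), total_duration=max(duration, 0.0))
        return cls(schedule=((0.0, duration, irradiance),), total_duration=duration)

    def irradiance_at(self, t: float) -> float:
        for start, stop, irr in self.schedule:
            if start <= t < stop:
                return irr
        return 0.0


@dataclass(frozen=True)
class MembraneTrajectory:
    """Recorded state trajectory of :func:`simulate_membrane`."""

    t: np.ndarray
    V: np.ndarray
    m_Q: np.ndarray
    h_Q: np.ndarray
    n_K: np.ndarray
    S: np.ndarray

    def __len__(self) -> int:
        return int(self.t.size)

    def state_at(self, i: int) -> MembraneState:
        return MembraneState(
            t=float(self.t[i]), V=float(self.V[i]), m_Q=float(self.m_Q[i]),
            h_Q=float(self.h_Q[i]), n_K=float(self.n_K[i]), S=float(self.S[i]),
        )

    def states(self) -> Iterable[MembraneState]:
        return (self.state_at(i) for i in range(len(self)))


def _sig(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x) if x < 500 else 0.0)
    return math.exp(x) / (1.0 + math.exp(x)) if x > -500 else 0.0


def _rhs(params: HHParams, t: float, y: tuple, irradiance: float) -> tuple:
    """Scalar right-hand side (hot path: plain floats, no array churn)."""
    V, m, h, n, S = y
    i_Q = params.g_Q * m * h * (V - params.E_Q)
    i_K = params.g_K * (n ** params.p_K) * (V - params.E_K)
    i_L = params.g_L * (V - params.E_L)
    dV = -(i_Q + i_K + i_L) / params.C_m

    m_inf = irradiance / (irradiance + params.I_half_Q)
    dm = (m_inf - m) / params.tau_act_Q

    if params.stress_half is not None and params.stress_half > 0:
        sg = _sig((S - params.stress_half) * params.stress_sharpness
                  / params.stress_half)
    else:
        sg = 0.0
    wl, wh = params.h_window_low, params.h_window_high
    in_window = _sig((V - wl.v_half) / wl.slope) * _sig((V - wh.v_half) / wh.slope)
    h_inf = max(1.0 - in_window, sg)
    if h_inf < h:
        dh = (h_inf - h) / params.tau_inact_Q
    else:
        # recovery rate blends from frozen to fast as the ROS latch engages
        rate = (1.0 - sg) / params.tau_recover_Q + sg / params.tau_habituate
        dh = (h_inf - h) * rate

    ng = params.n_gate
    n_inf = _sig((V - ng.v_half) / ng.slope) * (1.0 - sg)
    tau_n = params.tau_act_K if n_inf > n else params.tau_deact_K
    dn = (n_inf - n) / tau_n

    dS = params.alpha_ROS * irradiance - params.delta_ROS * S
    return (dV, dm, dh, dn, dS)


def simulate_membrane(
    params: HHParams,
    stim: StimulusProgram,
    initial: MembraneState | None = None,
    dt: float = 0.005,
    seed: int | None = None,
    record_dt: float = 0.1,
    noise_sd: float = 0.0,
    method: str = "fixed",
) -> tuple[MembraneTrajectory, ThTTrace]:
    """Integrate the membrane model and return (trajectory, ThT proxy trace).

    ``method="fixed"`` (default) uses fixed-step classical Runge-Kutta
    (RK4), bit-reproducible given identical inputs; ``method="adaptive"``
    uses an adaptive embedded Runge-Kutta pair (scipy RK45) at relative
    tolerance 1e-6, useful as an independent accuracy cross-check. ``seed``
    is only consulted when ``noise_sd`` > 0, in which case Gaussian
    measurement noise of that standard deviation (relative to the trace
    dynamic range) is added to the readout.

    Parameters
    ----------
    dt
        Integration step (min). Validated against the fastest time constant
        of ``params``; halving dt changes the trace by well under 0.1%.
    record_dt
        Cadence (min) at which states are recorded.

    Raises
    ------
    ValueError
        For an unstable dt or a stimulus shorter than dt.
    RuntimeError
        If the state becomes non-finite during integration (names the
        offending step and suggests a smaller dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau_min = params.fastest_timescale()
    if dt > tau_min / 4.0:
        raise ValueError(
            f"dt={dt} too large for stability: fastest time constant is "
            f"{tau_min:.4g} min; use dt <= {tau_min / 4.0:.4g}"
        )
    if stim.total_duration <= 0 or not stim.schedule:
        warnings.warn(
            "degenerate stimulus (zero-length schedule): returning the "
            "initial state only",
            stacklevel=2,
        )
        state0 = initial if initial is not None else MembraneState.resting(params)
        traj = MembraneTrajectory(
            t=np.array([state0.t]), V=np.array([state0.V]),
            m_Q=np.array([state0.m_Q]), h_Q=np.array([state0.h_Q]),
            n_K=np.array([state0.n_K]), S=np.array([state0.S]),
        )
        return traj, tht_readout(traj.V, times=traj.t, label="degenerate")
    if stim.total_duration < dt:
        raise ValueError("stimulus duration must be at least dt")

    if method not in ("fixed", "adaptive"):
        raise ValueError("method must be 'fixed' or 'adaptive'")
    state0 = initial if initial is not None else MembraneState.resting(params)
    if method == "adaptive":
        traj = _integrate_adaptive(params, stim, state0, record_dt)
        trace = tht_readout(traj.V, times=traj.t, label="hh", normalize=False)
        return traj, trace
    n_steps = int(round(stim.total_duration / dt))
    record_every = max(1, int(round(record_dt / dt)))

    y = (state0.V, state0.m_Q, state0.h_Q, state0.n_K, state0.S)
    t = state0.t
    rec_t = [t]
    rec_y = [y]
    for step in range(n_steps):
        irr = stim.irradiance_at(t)
        irr_mid = stim.irradiance_at(t + dt / 2.0)
        irr_end = stim.irradiance_at(t + dt)
        k1 = _rhs(params, t, y, irr)
        y2 = tuple(y[i] + dt / 2 * k1[i] for i in range(5))
        k2 = _rhs(params, t + dt / 2, y2, irr_mid)
        y3 = tuple(y[i] + dt / 2 * k2[i] for i in range(5))
        k3 = _rhs(params, t + dt / 2, y3, irr_mid)
        y4 = tuple(y[i] + dt * k3[i] for i in range(5))
        k4 = _rhs(params, t + dt, y4, irr_end)
        y = tuple(
            y[i] + dt / 6.0 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i])
            for i in range(5)
        )
        # gates live in [0,1], stress is non-negative; clamp RK overshoot
        y = (
            y[0],
            min(max(y[1], 0.0), 1.0),
            min(max(y[2], 0.0), 1.0),
            min(max(y[3], 0.0), 1.0),
            max(y[4], 0.0),
        )
        t = state0.t + (step + 1) * dt
        if not all(math.isfinite(v) for v in y):
            raise RuntimeError(
                f"integration became non-finite at step {step + 1} "
                f"(t={t:.4g} min); try a smaller dt"
            )
        if (step + 1) % record_every == 0 or step == n_steps - 1:
            rec_t.append(t)
            rec_y.append(y)

    arr = np.array(rec_y)
    traj = MembraneTrajectory(
        t=np.array(rec_t), V=arr[:, 0], m_Q=arr[:, 1], h_Q=arr[:, 2],
        n_K=arr[:, 3], S=arr[:, 4],
    )
    # raw (unnormalized) readout so downstream analysis can judge whether
    # the trace has any real dynamic range before min-max scaling
    trace = tht_readout(traj.V, times=traj.t, label="hh", normalize=False)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        span = float(trace.intensity.max() - trace.intensity.min())
        scale = noise_sd * (span if span > 0 else 1.0)
        noisy = np.clip(
            trace.intensity + rng.normal(0.0, scale, size=len(trace)), 0.0, None
        )
        trace = trace.with_intensity(noisy)
    return traj, trace


def _integrate_adaptive(
    params: HHParams,
    stim: StimulusProgram,
    state0: MembraneState,
    record_dt: float,
) -> MembraneTrajectory:
    """Adaptive RK45 integration at rtol 1e-6 (accuracy cross-check)."""
    from scipy.integrate import solve_ivp

    def rhs(t, y):
        return _rhs(params, t, tuple(y), stim.irradiance_at(t))

    t_eval = np.arange(
        state0.t, state0.t + stim.total_duration + record_dt / 2, record_dt
    )
    sol = solve_ivp(
        rhs,
        (state0.t, state0.t + stim.total_duration),
        [state0.V, state0.m_Q, state0.h_Q, state0.n_K, state0.S],
        method="RK45",
        t_eval=t_eval,
        rtol=1e-6,
        atol=1e-9,
        max_step=params.fastest_timescale(),
    )
    if not sol.success:
        raise RuntimeError(f"adaptive integration failed: {sol.message}")
    y = sol.y
    return MembraneTrajectory(
        t=sol.t,
        V=y[0],
        m_Q=np.clip(y[1], 0.0, 1.0),
        h_Q=np.clip(y[2], 0.0, 1.0),
        n_K=np.clip(y[3], 0.0, 1.0),
        S=np.clip(y[4], 0.0, None),
    )


def tht_readout(
    V_series: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray | None = None,
    v_ref: float = -60.0,
    v_thermal: float = THERMAL_VOLTAGE_MV,
    normalize: bool = True,
    label: str = "",
) -> ThTTrace:
    """Map a membrane-potential series to a ThT fluorescence proxy.

    ThT is a Nernstian voltage indicator: cationic dye accumulation follows
    F ~ exp(-(V - v_ref)/v_thermal), so hyperpolarization (more negative V)
    brightens the cell. With ``normalize`` the result is min-max scaled to
    [0, 1]; a constant series is returned as-is (raw Nernstian values)
    because min-max scaling is undefined for zero dynamic range.

    Raises
    ------
    ValueError
        If the series is empty or non-finite.
    """
    V = np.asarray(V_series, dtype=float)
    if V.size == 0:
        raise ValueError("empty membrane potential series")
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential series contains non-finite values")
    F = np.exp(-(V - v_ref) / v_thermal)
    if times is None:
        times_arr = np.arange(V.size, dtype=float)
    else:
        times_arr = np.asarray(times, dtype=float)
    span = F.max() - F.min()
    if normalize and span > 1e-12 * max(F.max(), 1.0):
        F = (F - F.min()) / span
        return ThTTrace(times=times_arr, intensity=F, label=label, normalized=True)
    return ThTTrace(times=times_arr, intensity=F, label=label, normalized=False)


def irradiance_from_power(
    power: float, field_number: float, magnification: float
) -> float:
    """Irradiance (uW/mm^2) delivered by a lens from measured power (uW).

    The field-of-view diameter is the objective field number divided by its
    magnification, so I = power / (pi * (FN / (2 mag))^2). E.g. 2.43 uW
    through a FN 26.5 mm, 60x objective gives ~15.9 uW/mm^2, the working
    irradiance used throughout.
    """
    if power < 0:
        raise ValueError("power must be non-negative")
    if field_number <= 0 or magnification <= 0:
        raise ValueError("field number and magnification must be positive")
    radius_mm = field_number / (2.0 * magnification)
    return power / (math.pi * radius_mm**2)


VARIANTS = ("wildtype", "delta_kch", "catalase", "ms_knockout")


def make_variant(params: HHParams, variant: str) -> HHParams:
    """Return parameters for a genetic/chemical variant of the model.

    * ``wildtype``: identity.
    * ``delta_kch``: Kch deletion, g_K = 0 (first peak, then a plateau with
      no repolarization).
    * ``catalase``: ROS scavenging, alpha_ROS = 0 (first peak only; the
      second hyperpolarization never occurs).
    * ``ms_knockout``: any mechanosensitive channel absent zeroes the
      product Q = MscK x MscL x MscS, so g_Q = 0 (no spike dynamics).
    """
    if variant == "wildtype":
        return params
    if variant == "delta_kch":
        return replace(params, g_K=0.0)
    if variant == "catalase":
        return replace(params, alpha_ROS=0.0)
    if variant == "ms_knockout":
        return replace(params, g_Q=0.0)
    raise ValueError(
        f"unknown variant {variant!r}; valid variants: {', '.join(VARIANTS)}"
    )
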