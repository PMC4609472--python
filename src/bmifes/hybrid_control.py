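"""Closed-loop FES elbow simulation: minimum-jerk reference, PID, nominal plant.

The reference trajectory is the minimum-jerk quintic

    q(t) = q0 + (qf - q0) (10 tau^3 - 15 tau^4 + 6 tau^5),  tau = t / T,

whose bell-shaped velocity peaks at 1.875 (qf - q0) / T at mid-movement.  A
PID controller, tuned with the classic Ziegler-Nichols closed-loop table,
converts tracking error into a stimulation amplitude (mA) that is hard-capped
at the per-subject comfort maximum.  Stimulation pulses are 40 Hz / 350 us;
only the amplitude is modulated.

The plant is a nominal linear second-order elbow (inertia + viscous damping)
driven through a first-order muscle-activation lag.  It is a desk-scale
stand-in for a human arm in a gravity-compensating exoskeleton — adequate for
exercising the control loop, with no claim of physiological fidelity (no
recruitment nonlinearity, no fatigue).  Angles are in degrees throughout;
signed commands select the muscle (positive -> extension/triceps,
negative -> flexion/biceps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classifier import DecisionTrace

__all__ = [
    "MinimumJerkRef",
    "PIDParams",
    "PIDState",
    "FESCommand",
    "PlantModel",
    "ReachLog",
    "minimum_jerk",
    "ziegler_nichols",
    "ultimate_gain",
    "pid_step",
    "simulate_reach",
    "trigger_movement",
    "FLEXED_ANGLE",
    "EXTENDED_ANGLE",
]

#: Nominal elbow angles (deg) for the flexed and extended arm postures.
FLEXED_ANGLE = 90.0
EXTENDED_ANGLE = 160.0


@dataclass(frozen=True)
class MinimumJerkRef:
    """Quintic reach from ``q0`` to ``qf`` (deg) over ``T`` seconds."""

    q0: float
    qf: float
    T: float = 2.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("movement duration must be positive")


@dataclass(frozen=True)
class PIDParams:
    Kp: float
    Ki: float = 0.0
    Kd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.Kp, self.Ki, self.Kd) < 0:
            raise ValueError("PID gains must be nonnegative")


@dataclass
class PIDState:
    integral: float = 0.0
    prev_error: float | None = None


@dataclass(frozen=True)
class FESCommand:
    """Stimulation pulse parameters; amplitude is the modulated quantity."""

    amplitude_max: float = 25.0     # mA, per-subject comfort limit
    frequency: float = 40.0         # Hz
    pulse_width: float = 350.0      # us
    muscle: str = "biceps"

    def __post_init__(self) -> None:
        if self.amplitude_max < 0:
            raise ValueError("amplitude_max must be nonnegative")


@dataclass(frozen=True)
class PlantModel:
    """Nominal linear elbow: inertia * qddot = gain * a - damping * qdot.

    ``gain`` maps activation (mA) to angular acceleration contribution
    (deg/s^2 per mA at unit inertia); ``activation_tau`` is the first-order
    muscle activation lag (s).
    """

    inertia: float = 1.0
    damping: float = 3.0
    gain: float = 15.0
    activation_tau: float = 0.08
    angle_limits: tuple[float, float] = (-45.0, 225.0)

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ValueError("inertia must be positive")
        if self.damping < 0:
            raise ValueError("damping must be nonnegative")


@dataclass
class ReachLog:
    t: np.ndarray
    q_ref: np.ndarray
    q: np.ndarray
    amplitude: np.ndarray
    muscle: str = ""
    command_time: float = 0.0

    def rmse(self) -> float:
        return float(np.sqrt(np.mean((self.q - self.q_ref) ** 2)))

    def to_delimited(self, path) -> None:
        arr = np.column_stack([self.t, self.q_ref, self.q, self.amplitude])
        np.savetxt(path, arr, fmt="%.5f", delimiter="\t",
                   header="t_s\tq_ref_deg\tq_deg\tamplitude_mA", comments="")


# --------------------------------------------------------------------------
# reference & tuning
# --------------------------------------------------------------------------

def minimum_jerk(ref: MinimumJerkRef, t: float | np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position (deg) and velocity (deg/s) at time(s) ``t``.

    Times outside [0, T] are clamped to the boundary values.
    """
    t = np.asarray(t, float)
    tau = np.clip(t / ref.T, 0.0, 1.0)
    d = ref.qf - ref.q0
    pos = ref.q0 + d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = d / ref.T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return pos, vel


def ziegler_nichols(Ku: float, Tu: float) -> PIDParams:
    """Classic closed-loop table: Kp=0.6 Ku, Ki=1.2 Ku/Tu, Kd=0.075 Ku Tu."""
    if Ku <= 0 or Tu <= 0:
        raise ValueError("Ku and Tu must be positive")
    return PIDParams(Kp=0.6 * Ku, Ki=1.2 * Ku / Tu, Kd=0.075 * Ku * Tu)


def ultimate_gain(plant: PlantModel = PlantModel()) -> tuple[float, float]:
    """Ultimate gain Ku and period Tu of the nominal plant under P control.

    For the linear plant G(s) = gain / [(J s + b) s (tau s + 1)] the phase
    crosses -180 deg at w = sqrt(b / (J tau)); Ku is 1/|G(jw)| there and
    Tu = 2 pi / w.  Closed form, hence exactly reproducible.
    """
    J, b, k, tau = (plant.inertia, plant.damping, plant.gain,
                    plant.activation_tau)
    w = math.sqrt(b / (J * tau))
    mag = k / (w * math.hypot(J * w, b) * math.hypot(1.0, w * tau))
    return 1.0 / mag, 2.0 * math.pi / w


# --------------------------------------------------------------------------
# controller & plant
# --------------------------------------------------------------------------

def pid_step(error: float, state: PIDState, params: PIDParams, dt: float,
             u_limit: float | None = None) -> tuple[float, PIDState]:
    """One discrete PID update with conditional-integration anti-windup.

    Returns the (unsaturated-output, new-state) pair; when ``u_limit`` is
    given, the integrator freezes whenever the output is saturated and the
    error pushes it further into saturation.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    deriv = 0.0 if state.prev_error is None else (error - state.prev_error) / dt
    integral = state.integral + error * dt
    u = params.Kp * error + params.Ki * integral + params.Kd * deriv
    if u_limit is not None and abs(u) > u_limit and u * error > 0:
        integral = state.integral  # anti-windup: do not accumulate further
        u = (params.Kp * error + params.Ki * integral + params.Kd * deriv)
    return u, PIDState(integral=integral, prev_error=error)


def simulate_reach(plant: PlantModel, ref: MinimumJerkRef, pid: PIDParams,
                   fes: FESCommand = FESCommand(), dt: float = 0.005,
                   duration: float | None = None,
                   hold_reference: bool = True) -> ReachLog:
    """Closed-loop reach from ``ref.q0``: PID on tracking error sets the
    (saturated) stimulation amplitude driving the nominal plant.

    The reference follows the minimum-jerk profile for ``ref.T`` seconds and
    then holds ``qf`` (settling phase).  Raises if the trajectory diverges
    beyond the plant's angle limits.
    """
    if dt > 0.010:
        raise ValueError("dt must be <= 10 ms")
    duration = 2.5 * ref.T + 2.0 if duration is None else duration
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    q_ref, _ = minimum_jerk(ref, t)
    if not hold_reference:
        q_ref = np.full(n, ref.q0)
    q = ref.q0
    qdot = 0.0
    a = 0.0  # signed activation, mA
    state = PIDState()
    qs = np.empty(n)
    amps = np.empty(n)
    lo, hi = plant.angle_limits
    for i in range(n):
        err = q_ref[i] - q
        u, state = pid_step(err, state, pid, dt, u_limit=fes.amplitude_max)
        u_sat = float(np.clip(u, -fes.amplitude_max, fes.amplitude_max))
        a += dt * (u_sat - a) / plant.activation_tau
        qddot = (plant.gain * a - plant.damping * qdot) / plant.inertia
        qdot += dt * qddot
        q += dt * qdot
        qs[i] = q
        amps[i] = abs(u_sat)
        if not (lo <= q <= hi) or not math.isfinite(q):
            raise RuntimeError(
                f"unstable configuration: angle {q:.1f} deg outside limits "
                f"({lo}, {hi}) at t={t[i]:.2f} s (gains {pid})")
    return ReachLog(t, q_ref, qs, amps, muscle=fes.muscle)


def trigger_movement(trace: DecisionTrace, arm_state: str = "flexed",
                     plant: PlantModel = PlantModel(),
                     pid: PIDParams | None = None,
                     fes: FESCommand = FESCommand(), T: float = 2.0,
                     max_window: float = 5.0, dt: float = 0.005
                     ) -> list[ReachLog]:
    """Launch one FES reach per actuated command in a decision trace.

    From a flexed arm the first command extends the elbow (triceps); the arm
    state flips after every actuated reach.  Suppressed (rest-period)
    commands never trigger stimulation.  A command arriving while a reach is
    still inside its movement window is queued until that window closes.
    """
    if pid is None:
        pid = ziegler_nichols(*ultimate_gain(plant))
    logs: list[ReachLog] = []
    state = arm_state
    busy_until = -math.inf
    for cmd in trace.commands:
        if cmd.suppressed:
            continue
        start = max(cmd.time, busy_until)
        if state == "flexed":
            ref = MinimumJerkRef(FLEXED_ANGLE, EXTENDED_ANGLE, T)
            muscle = "triceps"
            state = "extended"
        else:
            ref = MinimumJerkRef(EXTENDED_ANGLE, FLEXED_ANGLE, T)
            muscle = "biceps"
            state = "flexed"
        log = simulate_reach(plant, ref, pid, replace(fes, muscle=muscle),
                             dt=dt, duration=max_window)
        log.command_time = start
        logs.append(log)
        busy_until = start + max_window
    return logs
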