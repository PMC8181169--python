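"""Two-node honeybee aggregation model.

Young honeybees in a two-sided arena walk randomly, stop on encounters, and
rest for a temperature-dependent time.  Two robotic nodes (CASUs) heat or
cool their side, emit vibration (which lengthens resting) or a subtle airflow
(which shortens it), and sense nearby bees with noisy IR sensors.  The
population is tracked as two continuous compartments B_R, B_L whose exchange
flows are modulated by the local resting times, giving a mean-field picture
of BEECLUST-style aggregation and symmetry breaking.

Flow structure per side (all per second):

* individual stopping:  alpha * X * B_contra / tau_contra
* social stopping:      beta  * X * B_ipsi * B_contra / tau_contra

so a side gains bees in proportion to how quickly bees leave the opposite
side (1/tau) and, for the social term, to how many potential interaction
partners already sit on the gaining side (mass action).  The two ODEs are
exact mirror images, so B_R + B_L is conserved term by term.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from typing import Callable

from .core import NoiseStream, as_schedule, clamp_conserved_pair, rk4_step

__all__ = [
    "BeeParams",
    "BeeSchedule",
    "BeeController",
    "BeeModel",
    "resting_time",
    "individual_flows",
    "social_flows",
    "bee_derivatives",
    "casu_thermal_derivatives",
    "observe_bees",
    "feedback_target_update",
]

T_TARGET_MIN = 28.0
T_TARGET_MAX = 36.0


@dataclass
class BeeParams:
    """Bee and CASU parameters.

    The resting-time spans (tau_delta = 24 s over t_delta = 8 degC) anchor the
    linear resting-time law to the measured endpoints: 1 s at 28 degC and
    25 s at 36 degC.  The behavioural rates (alpha_bees, beta_bees,
    sigma_bees) and the CASU constants (lambda rates, deadband, feedback step,
    observation noise) are calibration defaults; see docs/methods.md.
    """

    alpha_bees: float = 0.1           # individual stopping probability
    beta_bees: float = 0.06           # social-contact rate, per bee
    sigma_bees: float = 0.9           # flow-noise half width, in [0, 1]
    tau_delta: float = 24.0           # resting-time span over t_delta, s
    t_delta: float = 8.0              # temperature span, degC
    t_min: float = 28.0               # temperature of minimal resting, degC
    t_ambient: float = 28.0           # arena ambient temperature, degC
    t_max: float = 36.0               # hottest CASU setting, degC
    lambda_active_heating: float = 0.1    # degC/s
    lambda_active_cooling: float = 0.01   # degC/s
    lambda_passive_cooling: float = 0.005  # degC/s per degC above ambient
    epsilon_temp: float = 0.5         # controller deadband, degC
    delta_temp: float = 1.0           # feedback step size, degC
    sigma_beecasu: float = 0.4        # one-sided observation noise scale
    obs_window: float = 30.0          # gliding-average window, s
    b_total: float = 12.0             # group size, bees

    def validate(self, dt: float = 1.0) -> None:
        for name in (
            "alpha_bees", "beta_bees", "tau_delta", "t_delta",
            "lambda_active_heating", "lambda_active_cooling",
            "lambda_passive_cooling", "epsilon_temp", "delta_temp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("sigma_bees", "sigma_beecasu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.b_total <= 0:
            raise ValueError("b_total must be positive")
        if self.t_min > 36.0:
            raise ValueError("t_min must not exceed 36 degC")
        ratio = self.obs_window / dt
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                f"obs_window={self.obs_window} must be a positive multiple of dt={dt}"
            )


def resting_time(t_local: float, phi: float, psi: float, params: BeeParams) -> float:
    """Resting time (s) after a stop at local temperature ``t_local``.

    Linear in temperature between the anchor points (1 s at t_min, scaling by
    tau_delta over t_delta degrees), shortened by airflow phi in [0, 1] and
    doubled at full vibration psi = 1.
    """
    if t_local < params.t_min - 1e-9:
        raise ValueError(
            f"resting time undefined below t_min={params.t_min} (got {t_local})"
        )
    t_local = max(t_local, params.t_min)
    base = 1.0 + (params.tau_delta / params.t_delta) * (t_local - params.t_min) * (1.0 - phi)
    return base * (1.0 + psi)


def individual_flows(
    b_r: float, b_l: float, tau_r: float, tau_l: float,
    alpha: float, x_r: float, x_l: float,
) -> tuple[float, float]:
    """Spontaneous-stopping flows (into_R, into_L), bees/s."""
    return alpha * x_r * b_l / tau_l, alpha * x_l * b_r / tau_r


def social_flows(
    b_r: float, b_l: float, tau_r: float, tau_l: float,
    beta: float, x_r: float, x_l: float,
) -> tuple[float, float]:
    """Mass-action social-stopping flows (into_R, into_L), bees/s."""
    return beta * x_r * b_r * b_l / tau_l, beta * x_l * b_l * b_r / tau_r


def bee_derivatives(
    b_r: float, b_l: float, tau_r: float, tau_l: float,
    params: BeeParams,
    x_indiv_r: float = 1.0, x_indiv_l: float = 1.0,
    x_social_r: float = 1.0, x_social_l: float = 1.0,
) -> tuple[float, float]:
    """(dB_R/dt, dB_L/dt); the pair sums to zero exactly."""
    ir, il = individual_flows(b_r, b_l, tau_r, tau_l, params.alpha_bees, x_indiv_r, x_indiv_l)
    sr, sl = social_flows(b_r, b_l, tau_r, tau_l, params.beta_bees, x_social_r, x_social_l)
    net = ir - il + sr - sl
    return net, -net


def casu_thermal_derivatives(
    t_side: float, t_target: float, params: BeeParams
) -> float:
    """dT/dt of one CASU side: passive decay towards ambient plus fixed-rate
    active heating/cooling outside the deadband."""
    d = -params.lambda_passive_cooling * (t_side - params.t_ambient)
    if t_target - t_side > params.epsilon_temp:
        d += params.lambda_active_heating
    elif t_side - t_target > params.epsilon_temp:
        d -= params.lambda_active_cooling
    return d


def observe_bees(
    b_r: float, b_l: float, params: BeeParams, x_obs_r: float, x_obs_l: float
) -> tuple[float, float]:
    """Noisy one-sided sensor counts: occlusion and blind spots can only make
    the CASU undercount, never overcount."""
    return (
        b_r * (1.0 - params.sigma_beecasu * x_obs_r),
        b_l * (1.0 - params.sigma_beecasu * x_obs_l),
    )


def feedback_target_update(
    obs_avg_r: float, obs_avg_l: float,
    t_r: float, t_l: float,
    mode: str, params: BeeParams,
) -> tuple[float, float]:
    """Feedback temperature targets from gliding-average bee counts.

    Positive mode: the side observing more bees steps its target up by
    delta_temp and the other steps down (reciprocal cross-inhibition).
    Negative mode: inverted.  Targets are clamped to [28, 36] degC.  On an
    exact tie both sides take the else-branch (step down / up respectively).
    """
    d = params.delta_temp
    if mode == "positive":
        step_r = d if obs_avg_r > obs_avg_l else -d
        step_l = d if obs_avg_r < obs_avg_l else -d
    elif mode == "negative":
        step_r = d if obs_avg_r < obs_avg_l else -d
        step_l = d if obs_avg_r > obs_avg_l else -d
    else:
        raise ValueError(f"unknown feedback mode {mode!r} (use 'positive' or 'negative')")
    tgt_r = min(T_TARGET_MAX, max(T_TARGET_MIN, t_r + step_r))
    tgt_l = min(T_TARGET_MAX, max(T_TARGET_MIN, t_l + step_l))
    return tgt_r, tgt_l


@dataclass
class BeeSchedule:
    """Time-indexed robot actuation.  Each entry is a constant or a callable
    of time; targets are ignored when a feedback controller is active."""

    psi_r: float | Callable[[float], float] = 0.0
    psi_l: float | Callable[[float], float] = 0.0
    phi_r: float | Callable[[float], float] = 0.0
    phi_l: float | Callable[[float], float] = 0.0
    t_target_r: float | Callable[[float], float] = 28.0
    t_target_l: float | Callable[[float], float] = 28.0

    def __post_init__(self) -> None:
        for name in ("psi_r", "psi_l", "phi_r", "phi_l",
                     "t_target_r", "t_target_l"):
            setattr(self, name, as_schedule(getattr(self, name)))


@dataclass
class BeeController:
    """Which temperature law the CASUs run: 'fixed' targets from the
    schedule, or closed-loop 'positive' / 'negative' feedback."""

    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "positive", "negative"):
            raise ValueError(f"unknown controller mode {self.mode!r}")


class BeeModel:
    """Coupled bee-population / CASU-temperature model for one replicate.

    State: (B_R, B_L, T_R, T_L), advanced jointly with classical RK4 at
    dt = 1 s, with all noise draws and controller decisions frozen within a
    step.  After each step the bee pair is clipped and rescaled to keep
    B_R + B_L = B_total exact, and temperatures are clipped to the CASUs'
    physical range [t_ambient, t_max].
    """

    units = "s"
    state_names = ("b_r", "b_l", "t_r", "t_l")
    columns = (
        "b_r", "b_l", "t_r", "t_l",
        "psi_r", "psi_l", "phi_r", "phi_l",
        "t_target_r", "t_target_l",
        "b_obs_r", "b_obs_l", "obs_avg_r", "obs_avg_l",
    )

    def __init__(
        self,
        params: BeeParams | None = None,
        schedule: BeeSchedule | None = None,
        controller: BeeController | None = None,
        initial_temp_r: float | None = None,
        initial_temp_l: float | None = None,
        dt: float = 1.0,
        noise_prefix: str = "",
    ):
        self.params = params or BeeParams()
        self.params.validate(dt)
        self.schedule = schedule or BeeSchedule()
        self.controller = controller or BeeController()
        # Fixed-temperature runs start pre-heated at the t=0 target (the
        # protocol heats the CASUs before releasing the bees); feedback runs
        # start at ambient.
        if initial_temp_r is None:
            initial_temp_r = (
                self.schedule.t_target_r(0.0)
                if self.controller.mode == "fixed" else self.params.t_ambient
            )
        if initial_temp_l is None:
            initial_temp_l = (
                self.schedule.t_target_l(0.0)
                if self.controller.mode == "fixed" else self.params.t_ambient
            )
        self._t0_r = float(initial_temp_r)
        self._t0_l = float(initial_temp_l)
        self._dt = dt
        self._prefix = noise_prefix
        self.begin_run(NoiseStream(0))

    # -- replicate-runner contract ----------------------------------------
    def begin_run(self, noise: NoiseStream) -> None:
        p = self.params
        self.noise = noise
        self.b_r = 0.5 * p.b_total
        self.b_l = 0.5 * p.b_total
        self.t_r = self._t0_r
        self.t_l = self._t0_l
        maxlen = int(round(p.obs_window / self._dt))
        # Gliding average warms up on the mean of the samples available so far.
        self._obs_buf_r: deque[float] = deque(maxlen=maxlen)
        self._obs_buf_l: deque[float] = deque(maxlen=maxlen)
        self._last = {
            "psi_r": self.schedule.psi_r(0.0), "psi_l": self.schedule.psi_l(0.0),
            "phi_r": self.schedule.phi_r(0.0), "phi_l": self.schedule.phi_l(0.0),
            "t_target_r": self.t_r, "t_target_l": self.t_l,
            "b_obs_r": self.b_r, "b_obs_l": self.b_l,
            "obs_avg_r": self.b_r, "obs_avg_l": self.b_l,
        }

    def initial_record(self) -> tuple[float, ...]:
        l = self._last
        return (
            self.b_r, self.b_l, self.t_r, self.t_l,
            l["psi_r"], l["psi_l"], l["phi_r"], l["phi_l"],
            l["t_target_r"], l["t_target_l"],
            l["b_obs_r"], l["b_obs_l"], l["obs_avg_r"], l["obs_avg_l"],
        )

    def conserved_total(self) -> float:
        return self.b_r + self.b_l

    def step(self, t: float, dt: float) -> tuple[float, ...]:
        p = self.params
        ns = self.noise
        pre = self._prefix

        # 1. draw this step's noise, frozen across the RK4 stages
        x_ind_r = ns.scaled_uniform(pre + "bee.indiv_r", p.sigma_bees)
        x_ind_l = ns.scaled_uniform(pre + "bee.indiv_l", p.sigma_bees)
        x_soc_r = ns.scaled_uniform(pre + "bee.social_r", p.sigma_bees)
        x_soc_l = ns.scaled_uniform(pre + "bee.social_l", p.sigma_bees)
        x_obs_r = ns.uniform01(pre + "bee.obs_r")
        x_obs_l = ns.uniform01(pre + "bee.obs_l")

        # 2. sense: noisy counts into the 30 s gliding averages
        b_obs_r, b_obs_l = observe_bees(self.b_r, self.b_l, p, x_obs_r, x_obs_l)
        self._obs_buf_r.append(b_obs_r)
        self._obs_buf_l.append(b_obs_l)
        avg_r = math.fsum(self._obs_buf_r) / len(self._obs_buf_r)
        avg_l = math.fsum(self._obs_buf_l) / len(self._obs_buf_l)

        # 3. control: temperature targets for this step
        if self.controller.mode == "fixed":
            tgt_r = self.schedule.t_target_r(t)
            tgt_l = self.schedule.t_target_l(t)
        else:
            tgt_r, tgt_l = feedback_target_update(
                avg_r, avg_l, self.t_r, self.t_l, self.controller.mode, p
            )

        # 4. realised stimuli
        psi_r = self.schedule.psi_r(t)
        psi_l = self.schedule.psi_l(t)
        phi_r = self.schedule.phi_r(t)
        phi_l = self.schedule.phi_l(t)

        # 5. integrate the joint (bees, temperatures) state
        def deriv(_t: float, y) -> tuple[float, float, float, float]:
            b_r, b_l, t_r, t_l = y
            tau_r = resting_time(max(t_r, p.t_min), phi_r, psi_r, p)
            tau_l = resting_time(max(t_l, p.t_min), phi_l, psi_l, p)
            db_r, db_l = bee_derivatives(
                b_r, b_l, tau_r, tau_l, p,
                x_ind_r, x_ind_l, x_soc_r, x_soc_l,
            )
            return (
                db_r, db_l,
                casu_thermal_derivatives(t_r, tgt_r, p),
                casu_thermal_derivatives(t_l, tgt_l, p),
            )

        y = rk4_step(
            (self.b_r, self.b_l, self.t_r, self.t_l), deriv, t, dt,
            state_names=self.state_names,
        )

        # 6. clamp: exact conservation of bees, physical temperature range
        self.b_r, self.b_l = clamp_conserved_pair(
            float(y[0]), float(y[1]), p.b_total, label="bees"
        )
        self.t_r = min(max(float(y[2]), p.t_ambient), p.t_max)
        self.t_l = min(max(float(y[3]), p.t_ambient), p.t_max)

        self._last = {
            "psi_r": psi_r, "psi_l": psi_l, "phi_r": phi_r, "phi_l": phi_l,
            "t_target_r": tgt_r, "t_target_l": tgt_l,
            "b_obs_r": b_obs_r, "b_obs_l": b_obs_l,
            "obs_avg_r": avg_r, "obs_avg_l": avg_l,
        }
        return self.initial_record()

    # -- analysis helpers --------------------------------------------------
    def with_params(self, **overrides) -> "BeeModel":
        return BeeModel(
            params=replace(self.params, **overrides),
            schedule=self.schedule,
            controller=self.controller,
            initial_temp_r=self._t0_r,
            initial_temp_l=self._t0_l,
            dt=self._dt,
            noise_prefix=self._prefix,
        )


def equilibrium_share(
    tau_r: float, tau_l: float, params: BeeParams, b_total: float | None = None
) -> float:
    """Zero-noise fixed point B_R* of the two-compartment flow system with
    constant resting times, from the quadratic dB_R/dt = 0.

    Solved by bracketing + bisection on [0, B_total]; used as the algebraic
    oracle for long zero-noise integrations.
    """
    b = params.b_total if b_total is None else b_total
    a_l = 1.0 / tau_l
    a_r = 1.0 / tau_r

    def f(b_r: float) -> float:
        b_l = b - b_r
        return (
            params.alpha_bees * (b_l * a_l - b_r * a_r)
            + params.beta_bees * b_r * b_l * (a_l - a_r)
        )

    lo, hi = 0.0, b
    flo = f(lo)
    # f(0) = alpha*B/tau_l > 0 and f(B) = -alpha*B/tau_r < 0: a root exists.
    if flo <= 0.0:
        return 0.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
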