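"""Ring-corridor zebrafish direction-choice model with robotic conspecifics.

A shoal of F_total zebrafish swims in a circular corridor either clockwise
(CW) or counter-clockwise (CCW).  Direction changes happen spontaneously
(only when a fish is alone, i.e. has no conspecific in its sight area) or
socially, by aligning with the perceived majority.  One or more robotic fish
can join the shoal; living fish accept the lure as a conspecific with
probability gamma_fish per encounter, so the robot enters the social terms
with weight n_robots * gamma_fish.  The robot's own direction R_CW(t) in
[0, 1] is a time budget set by an exogenous or closed-loop controller.

Perception is erroneous on both sides of the loop: fish misjudge their
neighbours' direction (sigma_fish), and the tracking software informing the
closed-loop robot miscounts the fish (sigma_fishrobot).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace
from .core import NoiseStream, clamp_conserved_pair, euler_step, rk4_step

__all__ = [
    "FishParams",
    "FishObservation",
    "FishModel",
    "ConstantRobot",
    "RandomSwitchingRobot",
    "ClosedLoopRobot",
    "grouping_probability",
    "individual_switch_flows",
    "perceive",
    "social_switch_flows",
    "fish_derivatives",
    "robot_track_fish",
    "robot_decide",
]


@dataclass
class FishParams:
    """Behavioural parameters; rates are per second.

    sight_ratio is the ratio of one fish's sight area to the arena area
    (geometry of the corridor gives between 1/3 and 1/7, on average 1/5), so
    with five or more agents present no fish is ever alone and only the
    social channel operates.  The rate defaults are calibration values; see
    docs/methods.md.
    """

    alpha_fish: float = 0.01       # spontaneous switch probability when alone
    beta_fish: float = 0.01        # social switching coefficient
    sigma_fish: float = 0.3        # fish perception-noise scale, in [0, 1]
    gamma_fish: float = 0.7        # robot acceptance coefficient, in [0, 1]
    sigma_fishrobot: float = 0.1   # tracking-software noise scale
    sight_ratio: float = 0.2       # A_sight / A_arena
    f_total: float = 6.0           # number of live fish
    n_robots: int = 0              # number of robotic fish

    def validate(self) -> None:
        for name in ("alpha_fish", "beta_fish", "sigma_fishrobot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma_fish", "gamma_fish"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.sight_ratio <= 1.0:
            raise ValueError("sight_ratio must lie in (0, 1]")
        if self.f_total < 0:
            raise ValueError("f_total must be >= 0")
        if self.n_robots < 0:
            raise ValueError("n_robots must be >= 0")

    @property
    def robot_weight(self) -> float:
        """Combined conspecific weight of the robots: n_robots * gamma."""
        return self.n_robots * self.gamma_fish


def grouping_probability(params: FishParams) -> tuple[float, float]:
    """(p_group, p_alone): probability that a fish has at least one
    conspecific (robot included, weighted by gamma) in sight."""
    p_group = min(1.0, (params.f_total + params.robot_weight) * params.sight_ratio)
    return p_group, 1.0 - p_group


def individual_switch_flows(
    f_cw: float, f_ccw: float, params: FishParams
) -> tuple[float, float]:
    """Spontaneous direction-switch flows (into_CW, into_CCW), fish/s."""
    _, p_alone = grouping_probability(params)
    return (
        params.alpha_fish * p_alone * f_ccw,
        params.alpha_fish * p_alone * f_cw,
    )


@dataclass(frozen=True)
class FishObservation:
    """Perceived fish counts by focal direction, and the tracker's view."""

    obs_cw_by_cw: float
    obs_ccw_by_cw: float
    obs_cw_by_ccw: float
    obs_ccw_by_ccw: float


def perceive(
    f_cw: float, f_ccw: float, r_cw: float, params: FishParams,
    x_cw_by_cw: float, x_ccw_by_cw: float,
    x_cw_by_ccw: float, x_ccw_by_ccw: float,
) -> FishObservation:
    """Erroneously perceived direction counts for CW- and CCW-swimming fish.

    Each focal group misattributes a noise-scaled share of the fish (and
    robot weight) in each direction; the "-1" excludes the focal fish itself
    from its own count.  With a fractional compartment below one
    fish-equivalent the raw expression can dip below zero, so perceived
    counts are floored at 0.
    """
    g = params.robot_weight
    r_ccw = 1.0 - r_cw
    s = params.sigma_fish
    seen_cw = f_cw + g * r_cw
    seen_ccw = f_ccw + g * r_ccw
    # errors made by CW-swimming fish
    e_ccw_by_cw = s * (seen_cw - 1.0) * x_cw_by_cw
    e_cw_by_cw = s * seen_ccw * x_ccw_by_cw
    # errors made by CCW-swimming fish
    e_ccw_by_ccw = s * seen_cw * x_cw_by_ccw
    e_cw_by_ccw = s * (seen_ccw - 1.0) * x_ccw_by_ccw
    return FishObservation(
        obs_cw_by_cw=max(0.0, seen_cw + e_cw_by_cw - e_ccw_by_cw),
        obs_ccw_by_cw=max(0.0, seen_ccw - e_cw_by_cw + e_ccw_by_cw),
        obs_cw_by_ccw=max(0.0, seen_cw + e_cw_by_ccw - e_ccw_by_ccw),
        obs_ccw_by_ccw=max(0.0, seen_ccw - e_cw_by_ccw + e_ccw_by_ccw),
    )


def social_switch_flows(
    f_cw: float, f_ccw: float, r_cw: float,
    obs: FishObservation, params: FishParams,
) -> tuple[float, float]:
    """Socially induced switch flows (into_CW, into_CCW), fish/s.

    Mass action: the flow into CW scales with the source population swimming
    CCW (robot weight included) and with the odds the CCW swimmers perceive
    in favour of CW; the +1 in the denominator is the focal fish itself.
    """
    g = params.robot_weight
    p_group, _ = grouping_probability(params)
    r_ccw = 1.0 - r_cw
    into_cw = (
        params.beta_fish * p_group * (f_ccw + g * r_ccw)
        * obs.obs_cw_by_ccw / (obs.obs_ccw_by_ccw + 1.0)
    )
    into_ccw = (
        params.beta_fish * p_group * (f_cw + g * r_cw)
        * obs.obs_ccw_by_cw / (obs.obs_cw_by_cw + 1.0)
    )
    return into_cw, into_ccw


def fish_derivatives(
    f_cw: float, f_ccw: float, r_cw: float,
    obs: FishObservation, params: FishParams,
) -> tuple[float, float]:
    """(dF_CW/dt, dF_CCW/dt); the pair sums to zero exactly."""
    i_cw, i_ccw = individual_switch_flows(f_cw, f_ccw, params)
    s_cw, s_ccw = social_switch_flows(f_cw, f_ccw, r_cw, obs, params)
    net = i_cw - i_ccw + s_cw - s_ccw
    return net, -net


def robot_track_fish(
    f_cw: float, f_ccw: float, params: FishParams,
    x_cw: float, x_ccw: float,
) -> tuple[float, float]:
    """Tracker-side observed direction proportions (prop_CW, prop_CCW).

    The counting error is antisymmetric (a fish miscounted out of one
    direction is counted into the other), so the proportions sum to one for
    every draw.
    """
    if params.f_total <= 0:
        raise ValueError("robot tracking requires f_total > 0")
    err_cw = params.sigma_fishrobot * (x_ccw * f_ccw - x_cw * f_cw)
    prop_cw = (f_cw + err_cw) / params.f_total
    return prop_cw, 1.0 - prop_cw


def robot_decide(prop_history, rng) -> float:
    """Closed-loop direction rule: follow the gliding-average majority;
    an empty history or an exact tie falls to a fair coin."""
    if len(prop_history) == 0:
        return 1.0 if rng.random() < 0.5 else 0.0
    mean = math.fsum(prop_history) / len(prop_history)
    if mean > 0.5:
        return 1.0
    if mean < 0.5:
        return 0.0
    return 1.0 if rng.random() < 0.5 else 0.0


# ---------------------------------------------------------------------------
# Robot controllers


class ConstantRobot:
    """Exogenous mode: the robots hold a fixed direction budget (F1)."""

    stochastic = False

    def __init__(self, r_cw: float = 1.0):
        if not 0.0 <= r_cw <= 1.0:
            raise ValueError("r_cw must lie in [0, 1]")
        self.r_cw = float(r_cw)

    def begin_run(self, noise: NoiseStream) -> None:
        pass

    def decide(self, t: float, model: "FishModel") -> float:
        return self.r_cw


class RandomSwitchingRobot:
    """Exogenous two-state machine flipping direction with probability
    p_switch in each time step (F2)."""

    stochastic = True

    def __init__(self, p_switch: float = 0.014):
        if not 0.0 <= p_switch <= 1.0:
            raise ValueError("p_switch must lie in [0, 1]")
        self.p_switch = float(p_switch)
        self.state = 1.0

    def begin_run(self, noise: NoiseStream) -> None:
        self._rng = noise.generator("robot.exogenous")
        self.state = 1.0 if self._rng.random() < 0.5 else 0.0

    def decide(self, t: float, model: "FishModel") -> float:
        if self._rng.random() < self.p_switch:
            self.state = 1.0 - self.state
        return self.state


class ClosedLoopRobot:
    """Majority-following mode (F3): each second the tracker reports one
    observed CW proportion; the robot follows the gliding average of the
    last ``window`` proportions, coin-flipping exact ties."""

    stochastic = True

    def __init__(self, window: int = 1):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = int(window)

    def begin_run(self, noise: NoiseStream) -> None:
        self._rng = noise.generator("robot.decision")
        self._props: deque[float] = deque(maxlen=self.window)

    def decide(self, t: float, model: "FishModel") -> float:
        prop_cw, _ = robot_track_fish(
            model.f_cw, model.f_ccw, model.params,
            model.noise.uniform01("robot.track_cw"),
            model.noise.uniform01("robot.track_ccw"),
        )
        self._props.append(prop_cw)
        model.last_tracked_prop = prop_cw
        return robot_decide(self._props, self._rng)


# ---------------------------------------------------------------------------


class FishModel:
    """Shoal-direction model for one replicate.

    State: (F_CW, F_CCW), advanced with RK4 (or explicit Euler via
    ``solver``) at dt = 1 s with noise, perception and the robot decision
    frozen within the step; the pair is re-clamped to F_total afterwards.
    """

    units = "s"
    state_names = ("f_cw", "f_ccw")
    columns = (
        "f_cw", "f_ccw", "r_cw",
        "obs_cw_by_cw", "obs_ccw_by_cw", "obs_cw_by_ccw", "obs_ccw_by_ccw",
        "tracked_prop_cw",
    )

    def __init__(
        self,
        params: FishParams | None = None,
        robot=None,
        solver: str = "rk4",
    ):
        self.params = params or FishParams()
        self.params.validate()
        if robot is None and self.params.n_robots > 0:
            robot = ConstantRobot(1.0)
        self.robot = robot
        if solver not in ("rk4", "euler"):
            raise ValueError("solver must be 'rk4' or 'euler'")
        self._stepper = rk4_step if solver == "rk4" else euler_step
        self.begin_run(NoiseStream(0))

    def begin_run(self, noise: NoiseStream) -> None:
        p = self.params
        self.noise = noise
        self.f_cw = 0.5 * p.f_total
        self.f_ccw = 0.5 * p.f_total
        self.r_cw = 0.0
        self.last_tracked_prop = math.nan
        self._last_obs = FishObservation(math.nan, math.nan, math.nan, math.nan)
        if self.robot is not None:
            self.robot.begin_run(noise)
            # realised initial budget (constant robots report immediately)
            if isinstance(self.robot, ConstantRobot):
                self.r_cw = self.robot.r_cw

    def initial_record(self) -> tuple[float, ...]:
        o = self._last_obs
        return (
            self.f_cw, self.f_ccw, self.r_cw,
            o.obs_cw_by_cw, o.obs_ccw_by_cw, o.obs_cw_by_ccw, o.obs_ccw_by_ccw,
            self.last_tracked_prop,
        )

    def conserved_total(self) -> float:
        return self.f_cw + self.f_ccw

    def step(self, t: float, dt: float) -> tuple[float, ...]:
        p = self.params
        ns = self.noise

        # 1. robot decides its direction budget for this second
        if self.robot is not None and p.n_robots > 0:
            self.r_cw = self.robot.decide(t, self)
        r_cw = self.r_cw

        # 2. fish perceive each other (and the robots), four draws per step
        if p.n_robots > 0 or p.sigma_fish > 0:
            obs = perceive(
                self.f_cw, self.f_ccw, r_cw, p,
                ns.uniform01("fish.obs_cw_by_cw"),
                ns.uniform01("fish.obs_ccw_by_cw"),
                ns.uniform01("fish.obs_cw_by_ccw"),
                ns.uniform01("fish.obs_ccw_by_ccw"),
            )
        else:
            obs = perceive(self.f_cw, self.f_ccw, r_cw, p, 0.0, 0.0, 0.0, 0.0)
        self._last_obs = obs

        # 3. integrate with frozen observation and robot state; the net flow
        # is source-limited (a compartment cannot lose more fish in one step
        # than it holds), which keeps the dt=1 update out of negative mass
        def deriv(_t: float, y) -> tuple[float, float]:
            d_cw, _ = fish_derivatives(float(y[0]), float(y[1]), r_cw, obs, p)
            cap_in = max(0.0, float(y[1])) / dt
            cap_out = max(0.0, float(y[0])) / dt
            net = min(max(d_cw, -cap_out), cap_in)
            return net, -net

        y = self._stepper(
            (self.f_cw, self.f_ccw), deriv, t, dt, state_names=self.state_names
        )

        # 4. clamp: exact conservation of fish
        self.f_cw, self.f_ccw = clamp_conserved_pair(
            float(y[0]), float(y[1]), p.f_total, label="fish"
        )
        return self.initial_record()

    def with_params(self, **overrides) -> "FishModel":
        return FishModel(
            params=replace(self.params, **overrides),
            robot=self.robot,
        )
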