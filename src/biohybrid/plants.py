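"""Growing bean-shoot model under robotic light control.

A single bean shoot grows at constant biomass influx rho_in into a central
stem compartment P_stem, which splits evenly into flexible mass on the left
and right sides (P_Lflex, P_Rflex).  Lateral mass moves between the sides by
phototropism (individual term, weighted by the light ratio Lambda) and by
circumnutation (social mass-action term with multiplicative Gaussian noise),
and leaves the modelled frame by outgrowth at rate rho_out.  The tip's
horizontal position is summarised by the inhomogeneity metric
Upsilon in (0, 1) (0.5 = perfectly upright stem).

The dynamics are a system of three difference equations at a 1-minute step;
the robots' combined light output is the single dimensionless ratio
Lambda(t) in [0, 1] (0 = all light on the left), set by a fixed value, a
positive/negative feedback law on Upsilon, or a binary target-tracking rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .core import (
    NoiseStream,
    PiecewiseConstant,
    SimulationClock,
    Trajectory,
    as_schedule,
    forward_difference_step,
    run_replicate,
)

__all__ = [
    "PlantParams",
    "LightSchedule",
    "PlantModel",
    "plant_fluxes",
    "inhomogeneity",
    "light_posfb",
    "light_negfb",
    "light_binary_target",
    "default_target_schedule",
    "run_target_tracking",
]


@dataclass
class PlantParams:
    """Growth and motion parameters (per-minute rates, dimensionless mass).

    rho_in / rho_out fix the equilibrium flexible mass rho_in/rho_out; the
    motion rates and noise scales are calibration defaults (docs/methods.md).
    """

    rho_in: float = 0.4          # biomass influx, mass/min
    rho_out: float = 0.01        # outgrowth rate, 1/min, in (0, 1)
    alpha_plant: float = 0.45    # phototropic rate, 1/min
    beta_plant: float = 0.01     # circumnutation rate, 1/(mass*min)
    sigma_plant: float = 0.5     # motion-noise s.d. (X ~ N(1, sigma))
    sigma_plantcasu: float = 0.05  # detection-noise s.d. (X ~ N(0, sigma))

    def validate(self) -> None:
        if self.rho_in <= 0:
            raise ValueError("rho_in must be positive")
        if not 0.0 < self.rho_out < 1.0:
            raise ValueError("rho_out must lie in (0, 1)")
        for name in ("alpha_plant", "beta_plant", "sigma_plant", "sigma_plantcasu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def inhomogeneity(p_r: float, p_l: float) -> float:
    """Left-right imbalance Upsilon in (0, 1); 0.5 iff P_R == P_L.

    The +1 in the denominator keeps the metric off the extremes and pins
    young (low-mass) shoots near the centre, like a short stem that cannot
    reach far sideways.
    """
    return 0.5 * ((p_r - p_l) / (p_r + p_l + 1.0) + 1.0)


def light_posfb(upsilon: float, x_detect: float) -> float:
    """Positive feedback: more detected plant mass draws more light to that
    side.  Clamped to [0, 1] after adding detection noise."""
    return min(1.0, max(0.0, upsilon + x_detect))


def light_negfb(upsilon: float, x_detect: float) -> float:
    """Negative feedback: light mirrors the detected imbalance, steering the
    tip back to centre.  Clamped to [0, 1]."""
    return min(1.0, max(0.0, 1.0 - upsilon + x_detect))


def light_binary_target(upsilon: float, gamma: float) -> float:
    """Binary target-tracking rule: tip left of the target => right light on
    (Lambda = 1), otherwise left light on (ties fall to the else branch)."""
    return 1.0 if upsilon < gamma else 0.0


def plant_fluxes(
    p_stem: float, p_r: float, p_l: float,
    lam: float, params: PlantParams,
    x_ind_r: float = 1.0, x_ind_l: float = 1.0,
    x_soc_r: float = 1.0, x_soc_l: float = 1.0,
) -> dict[str, float]:
    """All per-step flux terms at the current state.

    The lateral switch flows are reported both raw and as a net L->R transfer
    capped at the donor side's available mass (so compartments cannot go
    negative in one step); the cap moves mass only between the sides and thus
    never disturbs the stem/outgrowth balance.
    """
    growth_r = 0.5 * p_stem
    growth_l = 0.5 * p_stem
    sw_r_ind = params.alpha_plant * x_ind_r * p_l * lam
    sw_l_ind = params.alpha_plant * x_ind_l * p_r * (1.0 - lam)
    sw_r_soc = params.beta_plant * x_soc_r * p_l * p_r
    sw_l_soc = params.beta_plant * x_soc_l * p_l * p_r
    out_r = params.rho_out * p_r
    out_l = params.rho_out * p_l
    net_lr = sw_r_ind + sw_r_soc - sw_l_ind - sw_l_soc
    # donor-side cap: a side cannot export more than it holds after its own
    # growth input and outgrowth within one step
    if net_lr > 0.0:
        net_lr = min(net_lr, p_l + growth_l - out_l)
    else:
        net_lr = -min(-net_lr, p_r + growth_r - out_r)
    return {
        "growth_r": growth_r, "growth_l": growth_l,
        "switch_r_indiv": sw_r_ind, "switch_l_indiv": sw_l_ind,
        "switch_r_social": sw_r_soc, "switch_l_social": sw_l_soc,
        "outgrowth_r": out_r, "outgrowth_l": out_l,
        "net_lr": net_lr,
    }


@dataclass
class LightSchedule:
    """Which light law the robots run.

    mode 'fixed' uses ``lambda_fixed`` (constant or callable of time);
    'posfb'/'negfb' apply the feedback laws with detection noise;
    'binary_target' tracks the target trajectory ``gamma`` noise-free.
    """

    mode: str = "fixed"
    lambda_fixed: float | Callable[[float], float] = 0.5
    gamma: float | Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "posfb", "negfb", "binary_target"):
            raise ValueError(f"unknown light mode {self.mode!r}")
        self.lambda_fixed = as_schedule(self.lambda_fixed)
        if self.mode == "binary_target":
            if self.gamma is None:
                raise ValueError("binary_target mode requires a gamma trajectory")
            self.gamma = as_schedule(self.gamma)


class PlantModel:
    """Single-tip bean shoot for one replicate (difference equations,
    dt = 1 min).  Starts from an empty system: all compartments at zero."""

    units = "min"
    state_names = ("p_stem", "p_r", "p_l")
    columns = ("p_stem", "p_r", "p_l", "lam", "upsilon", "gamma")

    def __init__(
        self,
        params: PlantParams | None = None,
        light: LightSchedule | None = None,
    ):
        self.params = params or PlantParams()
        self.params.validate()
        self.light = light or LightSchedule()
        self.begin_run(NoiseStream(0))

    def begin_run(self, noise: NoiseStream) -> None:
        self.noise = noise
        self.p_stem = 0.0
        self.p_r = 0.0
        self.p_l = 0.0
        self._last_lam = math.nan
        self._last_gamma = math.nan

    def initial_record(self) -> tuple[float, ...]:
        return (
            self.p_stem, self.p_r, self.p_l,
            self._last_lam, inhomogeneity(self.p_r, self.p_l), self._last_gamma,
        )

    def conserved_total(self) -> float | None:
        return None  # open system: one source, two sinks

    def light_ratio(self, t: float, upsilon: float) -> tuple[float, float]:
        """(Lambda, Gamma) for this step; Gamma is NaN unless tracking."""
        mode = self.light.mode
        if mode == "fixed":
            return self.light.lambda_fixed(t), math.nan
        if mode == "binary_target":
            gamma = self.light.gamma(t)
            return light_binary_target(upsilon, gamma), gamma
        x = self.noise.normal("plant.detect", 0.0, self.params.sigma_plantcasu)
        if mode == "posfb":
            return light_posfb(upsilon, x), math.nan
        return light_negfb(upsilon, x), math.nan

    def step(self, t: float, dt: float) -> tuple[float, ...]:
        p = self.params
        ns = self.noise
        upsilon = inhomogeneity(self.p_r, self.p_l)
        lam, gamma = self.light_ratio(t, upsilon)

        fl = plant_fluxes(
            self.p_stem, self.p_r, self.p_l, lam, p,
            ns.normal("plant.indiv_r", 1.0, p.sigma_plant),
            ns.normal("plant.indiv_l", 1.0, p.sigma_plant),
            ns.normal("plant.social_r", 1.0, p.sigma_plant),
            ns.normal("plant.social_l", 1.0, p.sigma_plant),
        )
        delta = (
            p.rho_in - fl["growth_r"] - fl["growth_l"],
            fl["growth_r"] + fl["net_lr"] - fl["outgrowth_r"],
            fl["growth_l"] - fl["net_lr"] - fl["outgrowth_l"],
        )
        y = forward_difference_step(
            (self.p_stem, self.p_r, self.p_l), delta, dt, state_names=self.state_names
        )
        # the donor-side cap already prevents negative mass; the floor only
        # guards against rounding at exact zero
        self.p_stem = max(0.0, float(y[0]))
        self.p_r = max(0.0, float(y[1]))
        self.p_l = max(0.0, float(y[2]))

        self._last_lam = lam
        self._last_gamma = gamma
        return (
            self.p_stem, self.p_r, self.p_l,
            lam, inhomogeneity(self.p_r, self.p_l), gamma,
        )

    def with_params(self, **overrides) -> "PlantModel":
        return PlantModel(params=replace(self.params, **overrides), light=self.light)


def default_target_schedule() -> PiecewiseConstant:
    """Three-phase target trajectory for the tip-guidance showcase:
    Gamma = 0.85 until t = 640, 0.2 until t = 880, 0.5 until t = 1200 (min)."""
    return PiecewiseConstant([0.0, 641.0, 881.0], [0.85, 0.2, 0.5])


def run_target_tracking(
    params: PlantParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    gamma: Callable[[float], float] | None = None,
    t_end: float = 1200.0,
) -> Trajectory:
    """Run the binary target-tracking experiment: 1,200 one-minute steps from
    an empty system, logging state, Upsilon, Lambda and Gamma."""
    light = LightSchedule(mode="binary_target", gamma=gamma or default_target_schedule())
    model = PlantModel(params=params, light=light)
    clock = SimulationClock(dt=1.0, t_end=t_end, units="min")
    return run_replicate(model, clock, seed)
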