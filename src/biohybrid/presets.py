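"""Experiment presets binding models, schedules, controllers and analysis
windows to the in-silico protocols of the three organism studies.

Bees (two CASUs, dt = 1 s):

* ``b1_homog``    both sides fixed at 28 degC, 12 bees, 20 min, N=14
* ``b1_heterog``  36 degC vs 32 degC, 15 bees, 13 min, N=12
* ``b2_vibration``  vibration psi=0.1 on the left for t in (180, 360] s,
  12 bees, 6 min, N=17
* ``b3_airflow``  36 vs 32 degC; airflow phi_R=0.6 from a per-replicate
  onset drawn uniformly in minutes 13-15, 15 bees, 20 min, N=12
* ``b4_posFB`` / ``b4_negFB`` / ``b4_control``  closed-loop temperature
  feedback (or fixed 28/28), 12 bees, 20 min, N=14

Fish (ring corridor, dt = 1 s, 30 min):

* ``f1_pure``   6 fish, no robot, N=8
* ``f1_mixed``  3 fish + 3 robots swimming constantly CW, N=8
* ``f2_open_loop``  5 fish + 1 robot switching direction with p=0.014 per
  second, N=24
* ``f3_closed_loop``  5 fish + 1 majority-following robot, N=22

Plants (dt = 1 min):

* ``p1_target``  binary light guiding the tip through the three-phase target
  schedule (0.85 / 0.2 / 0.5), 1,200 min, single showcase run
* ``p1_posFB`` / ``p1_negFB``  feedback light laws, 1,200 min
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Callable

import numpy as np
import pandas as pd

from . import metrics
from .bees import BeeController, BeeModel, BeeParams, BeeSchedule
from .core import NoiseStream, PiecewiseConstant, SimulationClock, Trajectory, run_ensemble
from .fish import ClosedLoopRobot, ConstantRobot, FishModel, FishParams, RandomSwitchingRobot
from .plants import LightSchedule, PlantModel, PlantParams, default_target_schedule

__all__ = ["Preset", "PRESETS", "get_preset", "run_preset", "preset_names"]


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    organism: str                       # "bees" | "fish" | "plants"
    clock: SimulationClock
    n_replicates: int
    make_model: Callable[[int, np.random.SeedSequence, dict], object]
    summarize: Callable[[Trajectory], dict]
    analysis: dict

    def model(self, k: int = 0, seed=0, overrides: dict | None = None):
        if not isinstance(seed, np.random.SeedSequence):
            seed = np.random.SeedSequence(int(seed))
        return self.make_model(k, seed, overrides or {})


def _split_overrides(params_cls, overrides: dict) -> tuple[dict, dict]:
    names = {f.name for f in fields(params_cls)}
    p = {k: v for k, v in overrides.items() if k in names}
    extra = {k: v for k, v in overrides.items() if k not in names}
    return p, extra


def _bee_summary(traj: Trajectory, b_total: float, window, extra=None) -> dict:
    counts = metrics.sampled_counts(traj, interval=30.0, window=window)
    row = {
        "majority_fraction": metrics.majority_fraction(counts, b_total),
        "minority_fraction": metrics.minority_fraction(counts, b_total),
    }
    if extra:
        row.update(extra(traj))
    return row


def _bee_preset(
    name: str,
    description: str,
    t_end: float,
    n_replicates: int,
    b_total: float,
    window: tuple[float, float],
    schedule_builder: Callable[[NoiseStream, dict], BeeSchedule],
    controller_mode: str = "fixed",
    extra_summary: Callable[[Trajectory], dict] | None = None,
) -> Preset:
    clock = SimulationClock(dt=1.0, t_end=t_end, units="s")

    def make_model(k: int, seed: np.random.SeedSequence, overrides: dict) -> BeeModel:
        p_over, extra = _split_overrides(BeeParams, overrides)
        params = replace(BeeParams(b_total=b_total), **p_over)
        schedule = schedule_builder(NoiseStream(seed), extra)
        return BeeModel(
            params=params,
            schedule=schedule,
            controller=BeeController(mode=controller_mode),
        )

    def summarize(traj: Trajectory) -> dict:
        return _bee_summary(traj, b_total, window, extra_summary)

    return Preset(
        name, description, "bees", clock, n_replicates, make_model, summarize,
        analysis={"window": window, "interval": 30.0, "b_total": b_total},
    )


def _step_schedule(t_on: float, off_value: float, on_value: float):
    return PiecewiseConstant([0.0, t_on], [off_value, on_value])


def _b2_phase_summary(traj: Trajectory) -> dict:
    pre = metrics.sampled_counts(traj, interval=30.0, window=(0.0, 180.0))
    post = metrics.sampled_counts(traj, interval=30.0, window=(210.0, 360.0))
    total = traj["b_r"][0] + traj["b_l"][0]
    return {
        "left_fraction_pre": float(np.mean(pre["b_l"]) / total),
        "left_fraction_vibration": float(np.mean(post["b_l"]) / total),
    }


def _b3_phase_summary(traj: Trajectory) -> dict:
    total = traj["b_r"][0] + traj["b_l"][0]
    pre = metrics.sampled_counts(traj, interval=30.0, window=(600.0, 780.0))
    post = metrics.sampled_counts(traj, interval=30.0, window=(960.0, 1200.0))
    return {
        "warm_side_fraction_pre": float(np.mean(pre["b_r"]) / total),
        "warm_side_fraction_post": float(np.mean(post["b_r"]) / total),
    }


def _fish_preset(
    name: str,
    description: str,
    n_replicates: int,
    f_total: float,
    n_robots: int,
    robot_builder: Callable[[dict], object] | None,
) -> Preset:
    clock = SimulationClock(dt=1.0, t_end=1800.0, units="s")

    def make_model(k: int, seed: np.random.SeedSequence, overrides: dict) -> FishModel:
        p_over, extra = _split_overrides(FishParams, overrides)
        params = replace(FishParams(f_total=f_total, n_robots=n_robots), **p_over)
        robot = robot_builder(extra) if robot_builder is not None else None
        solver = extra.get("solver", "rk4")
        return FishModel(params=params, robot=robot, solver=solver)

    def summarize(traj: Trajectory) -> dict:
        fish_budget, robot_budget = metrics.direction_time_budget(traj, f_total)
        return {"cw_time_budget": fish_budget, "robot_cw_budget": robot_budget}

    return Preset(
        name, description, "fish", clock, n_replicates, make_model, summarize,
        analysis={"f_total": f_total, "n_robots": n_robots},
    )


def _plant_preset(
    name: str, description: str, light_mode: str, n_replicates: int
) -> Preset:
    clock = SimulationClock(dt=1.0, t_end=1200.0, units="min")

    def make_model(k: int, seed: np.random.SeedSequence, overrides: dict) -> PlantModel:
        p_over, extra = _split_overrides(PlantParams, overrides)
        params = replace(PlantParams(), **p_over)
        if light_mode == "binary_target":
            light = LightSchedule(
                mode="binary_target",
                gamma=extra.get("gamma", default_target_schedule()),
            )
        else:
            light = LightSchedule(mode=light_mode)
        return PlantModel(params=params, light=light)

    def summarize(traj: Trajectory) -> dict:
        ups = traj["upsilon"]
        lam = traj["lam"]
        row = {
            "final_upsilon": float(ups[-1]),
            "final_abs_imbalance": float(abs(ups[-1] - 0.5)),
            "switch_count": metrics.switch_count(lam),
        }
        if light_mode == "binary_target":
            t = traj.times
            for label, (a, b) in {
                "I": (100.0, 640.0), "II": (641.0, 880.0), "III": (881.0, 1200.0),
            }.items():
                m = (t >= a) & (t <= b)
                row[f"switches_per_100_phase_{label}"] = (
                    metrics.switch_count(lam[m]) / max(1.0, (b - a) / 100.0)
                )
                row[f"mean_upsilon_phase_{label}"] = float(np.mean(ups[m]))
            late = (t >= 400.0) & (t <= 640.0)
            row["late_phase_I_mean_upsilon"] = float(np.mean(ups[late]))
        return row

    return Preset(
        name, description, "plants", clock, n_replicates, make_model, summarize,
        analysis={"light_mode": light_mode},
    )


def _build_presets() -> dict[str, Preset]:
    presets = [
        _bee_preset(
            "b1_homog",
            "Natural symmetry breaking: both CASUs fixed at 28 degC",
            t_end=1200.0, n_replicates=14, b_total=12.0, window=(480.0, 780.0),
            schedule_builder=lambda ns, o: BeeSchedule(t_target_r=28.0, t_target_l=28.0),
        ),
        _bee_preset(
            "b1_heterog",
            "Temperature choice: 36 degC (right) vs 32 degC (left)",
            t_end=780.0, n_replicates=12, b_total=15.0, window=(480.0, 780.0),
            schedule_builder=lambda ns, o: BeeSchedule(t_target_r=36.0, t_target_l=32.0),
        ),
        _bee_preset(
            "b2_vibration",
            "Vibration-induced aggregation: psi=0.1 on the left from t=181 s",
            t_end=360.0, n_replicates=17, b_total=12.0, window=(210.0, 360.0),
            schedule_builder=lambda ns, o: BeeSchedule(
                t_target_r=28.0, t_target_l=28.0,
                psi_l=_step_schedule(181.0, 0.0, o.get("psi_active", 0.1)),
            ),
            extra_summary=_b2_phase_summary,
        ),
        _bee_preset(
            "b3_airflow",
            "Decision reversal by airflow at the warm (36 degC) CASU",
            t_end=1200.0, n_replicates=12, b_total=15.0, window=(960.0, 1200.0),
            schedule_builder=lambda ns, o: BeeSchedule(
                t_target_r=36.0, t_target_l=32.0,
                phi_r=_step_schedule(
                    o.get(
                        "t_airflow",
                        780.0 + 120.0 * ns.uniform01("schedule.t_airflow"),
                    ),
                    0.0, o.get("phi_active", 0.6),
                ),
            ),
            extra_summary=_b3_phase_summary,
        ),
        _bee_preset(
            "b4_posFB",
            "Closed loop, positive feedback: crowded side warms up",
            t_end=1200.0, n_replicates=14, b_total=12.0, window=(900.0, 1200.0),
            schedule_builder=lambda ns, o: BeeSchedule(),
            controller_mode="positive",
        ),
        _bee_preset(
            "b4_negFB",
            "Closed loop, negative feedback: crowded side cools down",
            t_end=1200.0, n_replicates=14, b_total=12.0, window=(900.0, 1200.0),
            schedule_builder=lambda ns, o: BeeSchedule(),
            controller_mode="negative",
        ),
        _bee_preset(
            "b4_control",
            "Control for B4: both targets fixed at 28 degC",
            t_end=1200.0, n_replicates=14, b_total=12.0, window=(900.0, 1200.0),
            schedule_builder=lambda ns, o: BeeSchedule(t_target_r=28.0, t_target_l=28.0),
        ),
        _fish_preset(
            "f1_pure", "Pure shoal of 6 fish, no robot",
            n_replicates=8, f_total=6.0, n_robots=0, robot_builder=None,
        ),
        _fish_preset(
            "f1_mixed", "3 fish + 3 robots swimming constantly clockwise",
            n_replicates=8, f_total=3.0, n_robots=3,
            robot_builder=lambda o: ConstantRobot(o.get("r_cw", 1.0)),
        ),
        _fish_preset(
            "f2_open_loop",
            "5 fish + 1 robot switching direction with p=0.014 per second",
            n_replicates=24, f_total=5.0, n_robots=1,
            robot_builder=lambda o: RandomSwitchingRobot(o.get("p_switch", 0.014)),
        ),
        _fish_preset(
            "f3_closed_loop",
            "5 fish + 1 robot following the observed fish majority",
            n_replicates=22, f_total=5.0, n_robots=1,
            robot_builder=lambda o: ClosedLoopRobot(o.get("window", 1)),
        ),
        _plant_preset(
            "p1_target",
            "Binary light guiding the tip through targets 0.85 / 0.2 / 0.5",
            "binary_target", n_replicates=1,
        ),
        _plant_preset(
            "p1_posFB", "Positive light feedback on detected plant mass",
            "posfb", n_replicates=14,
        ),
        _plant_preset(
            "p1_negFB", "Negative light feedback on detected plant mass",
            "negfb", n_replicates=14,
        ),
    ]
    return {p.name: p for p in presets}


PRESETS: dict[str, Preset] = _build_presets()


def preset_names() -> list[str]:
    return list(PRESETS)


def get_preset(name: str) -> Preset:
    key = name.lower()
    for k, v in PRESETS.items():
        if k.lower() == key:
            return v
    raise KeyError(
        f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}"
    )


def run_preset(
    name: str,
    n_replicates: int | None = None,
    base_seed: int = 0,
    overrides: dict | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Run a named experiment preset for ``n_replicates`` seeded replicates
    and return (trajectories, one-row-per-replicate summary)."""
    preset = get_preset(name)
    n = preset.n_replicates if n_replicates is None else int(n_replicates)
    ov = overrides or {}

    def factory(k: int, seed: np.random.SeedSequence):
        return preset.make_model(k, seed, ov)

    trajs, summary = run_ensemble(
        factory, preset.clock, n, base_seed, summarize=preset.summarize
    )
    summary.insert(0, "preset", preset.name)
    summary.insert(2, "seed", [f"({base_seed},{k})" for k in range(n)])
    return trajs, summary
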