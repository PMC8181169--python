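"""Summary statistics over trajectories and replicate ensembles.

All metrics are pure functions of trajectories (no hidden state), matching
the experimental analysis protocols: bees are counted at 30-s intervals over
a fixed analysis window and reported as majority/minority fractions of the
group; fish and robot directions are reported as time budgets; the robot-
group relationship across replicates is a Pearson correlation of budgets.

Conventions (frozen by tests): sampling windows include both endpoints; the
majority side is evaluated per sampling instant and then averaged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Trajectory

__all__ = [
    "sampled_counts",
    "majority_fraction",
    "minority_fraction",
    "direction_time_budget",
    "robot_group_correlation",
    "switch_count",
]


def sampled_counts(
    traj: Trajectory,
    interval: float = 30.0,
    window: tuple[float, float] = (480.0, 780.0),
    columns: tuple[str, str] = ("b_r", "b_l"),
) -> pd.DataFrame:
    """Counts on each side at ``interval`` spacing across ``window``
    (both endpoints included)."""
    t0, t1 = window
    if t0 < traj.times[0] - 1e-9 or t1 > traj.times[-1] + 1e-9:
        raise ValueError(
            f"window {window} not contained in trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    sample_times = np.arange(t0, t1 + 0.5 * interval, interval)
    idx = np.searchsorted(traj.times, sample_times - 1e-9)
    out = {"time": traj.times[idx]}
    for col in columns:
        out[col] = traj[col][idx]
    return pd.DataFrame(out)


def majority_fraction(counts: pd.DataFrame | np.ndarray, total: float) -> float:
    """Mean over sampling instants of (bees on the majority side) / total."""
    arr = _pair_array(counts)
    return float(np.mean(np.max(arr, axis=1)) / total)


def minority_fraction(counts: pd.DataFrame | np.ndarray, total: float) -> float:
    arr = _pair_array(counts)
    return float(np.mean(np.min(arr, axis=1)) / total)


def _pair_array(counts) -> np.ndarray:
    if isinstance(counts, pd.DataFrame):
        cols = [c for c in counts.columns if c != "time"]
        arr = counts[cols].to_numpy(dtype=float)
    else:
        arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a (n_samples, 2) count array")
    return arr


def direction_time_budget(
    traj: Trajectory, f_total: float | None = None
) -> tuple[float, float]:
    """(fish CW time budget, robot CW time budget): time averages of
    F_CW / F_total and of R_CW over the whole trajectory."""
    f_cw = traj["f_cw"]
    if f_total is None:
        f_total = float(f_cw[0] + traj["f_ccw"][0])
    fish_budget = float(np.mean(f_cw) / f_total)
    r = traj["r_cw"]
    robot_budget = float(np.mean(r[np.isfinite(r)])) if np.any(np.isfinite(r)) else float("nan")
    return fish_budget, robot_budget


def robot_group_correlation(
    summary: pd.DataFrame,
    robot_col: str = "robot_cw_budget",
    fish_col: str = "cw_time_budget",
) -> float:
    """Pearson correlation across replicates between the robot's and the
    fish group's CW time budgets."""
    if len(summary) < 3:
        raise ValueError("need at least 3 replicates for a correlation")
    x = summary[robot_col].to_numpy(dtype=float)
    y = summary[fish_col].to_numpy(dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def switch_count(values: np.ndarray, threshold: float = 0.5) -> int:
    """Number of side switches in a light/direction signal: sign changes of
    (value - threshold), ignoring NaN entries."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    side = np.sign(v - threshold)
    side = side[side != 0]
    if side.size < 2:
        return 0
    return int(np.sum(side[1:] != side[:-1]))
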