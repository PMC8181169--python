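"""Shared simulation machinery: clocks, seeded noise streams, fixed-step
integrators and the replicate/ensemble runners used by all organism models.

The organism models advance in fixed steps (1 s for bees and fish, 1 min for
plants).  All stochastic terms are drawn once per step from named substreams
and held frozen across the stages of one integration step, mirroring the
discrete sense-and-act cadence of the physical robotic nodes.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationClock",
    "NoiseStream",
    "Trajectory",
    "rk4_step",
    "forward_difference_step",
    "run_replicate",
    "run_ensemble",
    "replicate_seed_sequence",
    "clamp_conserved_pair",
    "PiecewiseConstant",
    "as_schedule",
]


@dataclass(frozen=True)
class SimulationClock:
    """Fixed-step clock.  ``dt`` and ``t_end`` share one unit per model
    (seconds for bees/fish, minutes for plants); no implicit conversion."""

    dt: float
    t_end: float
    units: str = "s"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be positive, got {self.t_end}")
        ratio = self.t_end / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"t_end={self.t_end} is not an integer multiple of dt={self.dt}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


class NoiseStream:
    """Named, independent random substreams derived from one seed.

    Each draw site (e.g. ``"bee.indiv_R"``) gets its own ``numpy`` generator,
    spawned from ``SeedSequence(seed, spawn_key=(crc32(site),))``.  The same
    (seed, site) pair therefore yields a bit-identical draw sequence on every
    run, and distinct sites are statistically independent.
    """

    def __init__(self, seed: int | np.random.SeedSequence):
        if isinstance(seed, np.random.SeedSequence):
            self._ss = seed
        else:
            self._ss = np.random.SeedSequence(int(seed))
        self._gens: dict[str, np.random.Generator] = {}

    def generator(self, site: str) -> np.random.Generator:
        gen = self._gens.get(site)
        if gen is None:
            key = zlib.crc32(site.encode("utf-8"))
            ss = np.random.SeedSequence(
                entropy=self._ss.entropy,
                spawn_key=tuple(self._ss.spawn_key) + (key,),
            )
            gen = np.random.default_rng(ss)
            self._gens[site] = gen
        return gen

    # Convenience draws, one value per call -------------------------------
    def uniform01(self, site: str) -> float:
        """One U(0, 1) draw."""
        return float(self.generator(site).random())

    def scaled_uniform(self, site: str, sigma: float) -> float:
        """One U(1 - sigma, 1 + sigma) draw (flow noise of the bee model)."""
        return 1.0 + sigma * (2.0 * self.generator(site).random() - 1.0)

    def normal(self, site: str, mu: float, sigma: float) -> float:
        if sigma == 0.0:
            return float(mu)
        return float(mu + sigma * self.generator(site).standard_normal())


def replicate_seed_sequence(base_seed: int, k: int) -> np.random.SeedSequence:
    """Seed for replicate ``k``: splittable ``SeedSequence(base, spawn_key=(k,))``.

    Guarantees collision-free, independent substreams across replicates
    without arithmetic on raw seeds.
    """
    return np.random.SeedSequence(int(base_seed), spawn_key=(int(k),))


@dataclass
class Trajectory:
    """Per-step record of one seeded replicate: states, realised stimuli,
    observations and controller decisions, all vectors of length n_steps+1."""

    times: np.ndarray
    columns: tuple[str, ...]
    data: np.ndarray
    units: str = "s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.times.size, len(self.columns)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{self.times.size} times x {len(self.columns)} columns"
            )

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[:, self.columns.index(column)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.columns))
        df.insert(0, "time", self.times)
        return df


def _check_finite(vec: np.ndarray, names: Sequence[str] | None, what: str) -> None:
    if np.all(np.isfinite(vec)):
        return
    bad = int(np.flatnonzero(~np.isfinite(np.atleast_1d(vec)))[0])
    label = names[bad] if names is not None and bad < len(names) else f"component {bad}"
    raise ArithmeticError(f"non-finite {what} in state component '{label}'")


def rk4_step(
    state: np.ndarray,
    deriv: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    dt: float,
    state_names: Sequence[str] | None = None,
) -> np.ndarray:
    """One classical Runge-Kutta 4th-order step.

    ``deriv(t, y)`` must be evaluable at the four stage points; any stochastic
    inputs must already be frozen inside the closure so all four stages see
    identical coefficients.
    """
    y = np.asarray(state, dtype=float)
    k1 = np.asarray(deriv(t, y), dtype=float)
    _check_finite(k1, state_names, "derivative")
    k2 = np.asarray(deriv(t + 0.5 * dt, y + 0.5 * dt * k1), dtype=float)
    k3 = np.asarray(deriv(t + 0.5 * dt, y + 0.5 * dt * k2), dtype=float)
    k4 = np.asarray(deriv(t + dt, y + dt * k3), dtype=float)
    _check_finite(k4, state_names, "derivative")
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def euler_step(
    state: np.ndarray,
    deriv: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    dt: float,
    state_names: Sequence[str] | None = None,
) -> np.ndarray:
    """One explicit Euler step (alternative fish solver)."""
    y = np.asarray(state, dtype=float)
    k1 = np.asarray(deriv(t, y), dtype=float)
    _check_finite(k1, state_names, "derivative")
    return y + dt * k1


def forward_difference_step(
    state: np.ndarray,
    delta: np.ndarray,
    dt: float = 1.0,
    state_names: Sequence[str] | None = None,
) -> np.ndarray:
    """One step of a difference-equation system: ``state + dt * delta``.

    Used by the plant model, whose dynamics are defined directly as per-step
    differences rather than as an ODE.
    """
    d = np.asarray(delta, dtype=float)
    _check_finite(d, state_names, "difference")
    return np.asarray(state, dtype=float) + dt * d


def clamp_conserved_pair(
    a: float, b: float, total: float, warn_tol: float = 1e-6, label: str = ""
) -> tuple[float, float]:
    """Clip a two-compartment pair to non-negative values and rescale so the
    pair sums exactly to ``total``.

    At a 1 s step the flow terms can transiently overshoot a compartment's
    content; this post-step correction restores conservation of mass.  A
    correction larger than ``warn_tol * total`` triggers a warning because it
    indicates the step size is too coarse for the chosen rates.
    """
    a2, b2 = max(a, 0.0), max(b, 0.0)
    s = a2 + b2
    if s <= 0.0 or not np.isfinite(total / s):
        return 0.5 * total, 0.5 * total
    a3 = min(a2 * (total / s), total)  # rounding guard: keep the pair in [0, total]
    b3 = total - a3
    err = abs(a3 - a) + abs(b3 - b)
    if err > warn_tol * max(total, 1.0):
        warnings.warn(
            f"conservation clamp moved {err:.3g} of {total:.3g} {label}".strip(),
            RuntimeWarning,
            stacklevel=2,
        )
    return a3, b3


class PiecewiseConstant:
    """Right-continuous piecewise-constant schedule: value of the last
    breakpoint with ``t >= time``."""

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        if len(times) != len(values) or len(times) == 0:
            raise ValueError("times and values must be equal-length, non-empty")
        order = np.argsort(times, kind="stable")
        self.times = np.asarray(times, dtype=float)[order]
        self.values = np.asarray(values, dtype=float)[order]

    def __call__(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            return float(self.values[0])
        return float(self.values[idx])

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


def as_schedule(x) -> Callable[[float], float]:
    """Lift a constant to a schedule; pass callables through."""
    if callable(x):
        return x
    val = float(x)
    return lambda t: val


class OrganismModel(Protocol):
    """Contract every organism model fulfils for the replicate runner."""

    columns: tuple[str, ...]
    units: str

    def begin_run(self, noise: NoiseStream) -> None: ...

    def initial_record(self) -> tuple[float, ...]: ...

    def step(self, t: float, dt: float) -> tuple[float, ...]: ...

    def conserved_total(self) -> float | None: ...


def run_replicate(
    model: OrganismModel,
    clock: SimulationClock,
    seed: int | np.random.SeedSequence,
) -> Trajectory:
    """Run one seeded replicate: per step draw noise -> sense -> control ->
    integrate -> clamp, recording every quantity the model exposes.

    Deterministic given (model configuration, seed).
    """
    if getattr(model, "units", clock.units) != clock.units:
        raise ValueError(
            f"model units {model.units!r} do not match clock units {clock.units!r}"
        )
    validate = getattr(model, "validate_clock", None)
    if validate is not None:
        validate(clock)
    noise = NoiseStream(seed)
    model.begin_run(noise)
    n = clock.n_steps
    data = np.empty((n + 1, len(model.columns)), dtype=float)
    data[0] = model.initial_record()
    dt = clock.dt
    for k in range(n):
        data[k + 1] = model.step(k * dt, dt)
    meta = {"seed": seed if isinstance(seed, int) else repr(seed)}
    return Trajectory(clock.times, tuple(model.columns), data, units=clock.units, meta=meta)


def run_ensemble(
    model_factory: Callable[[int, np.random.SeedSequence], OrganismModel],
    clock: SimulationClock,
    n_replicates: int,
    base_seed: int,
    summarize: Callable[[Trajectory], dict] | None = None,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Run ``n_replicates`` independent replicates.

    Replicate ``k`` uses the splittable seed ``SeedSequence(base_seed, (k,))``
    and a freshly built model (so per-replicate schedule draws, e.g. a random
    stimulus onset time, stay independent).  Returns the trajectories and a
    summary table with one row per replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    trajectories: list[Trajectory] = []
    rows: list[dict] = []
    for k in range(n_replicates):
        ss = replicate_seed_sequence(base_seed, k)
        model = model_factory(k, ss)
        traj = run_replicate(model, clock, ss)
        traj.meta.update({"replicate": k, "base_seed": base_seed})
        trajectories.append(traj)
        row = {"replicate": k, "base_seed": base_seed}
        if summarize is not None:
            row.update(summarize(traj))
        rows.append(row)
    return trajectories, pd.DataFrame(rows)
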