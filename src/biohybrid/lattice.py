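"""Lattice scale-up: a grid of two-compartment bee units coupled to their
nearest neighbours by diffusion flows of non-resting bees.

Each lattice node is one full bee/CASU unit (its own parameters, schedule
and controller).  After every node advances one step of its own dynamics,
neighbouring nodes exchange bees side-by-side: the flow from node i to
node j on side s is ``d_coupling * B_i_s / tau_i_s`` per neighbour, i.e.
proportional to the momentarily mobile (non-resting) fraction.  The exchange
is antisymmetric pair by pair, so the global bee total is conserved exactly.

Neighbourhood is von Neumann (4-neighbour) with reflecting boundaries; the
flow law and boundary handling are this module's extrapolation of the
building-block idea, not a calibrated model.  A 1x1 grid degenerates to the
plain bee model, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .bees import BeeController, BeeModel, BeeParams, BeeSchedule, resting_time
from .core import NoiseStream

__all__ = ["LatticeConfig", "LatticeModel"]


@dataclass
class LatticeConfig:
    n_rows: int = 1
    n_cols: int = 1
    d_coupling: float = 0.0   # inter-node diffusion rate, per second
    params: BeeParams = field(default_factory=BeeParams)
    # optional per-node overrides keyed by (row, col)
    schedules: dict[tuple[int, int], BeeSchedule] = field(default_factory=dict)
    controllers: dict[tuple[int, int], BeeController] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.d_coupling < 0:
            raise ValueError("d_coupling must be >= 0")


class LatticeModel:
    """Grid of bee units with nearest-neighbour diffusion coupling."""

    units = "s"

    def __init__(self, config: LatticeConfig, dt: float = 1.0):
        self.config = config
        self.nodes: list[BeeModel] = []
        single = config.n_rows * config.n_cols == 1
        for r in range(config.n_rows):
            for c in range(config.n_cols):
                # a single node replays the standalone model's exact noise
                # substreams (degeneracy convention); larger grids get one
                # independent substream family per node
                prefix = "" if single else f"node{r}_{c}:"
                self.nodes.append(
                    BeeModel(
                        params=config.params,
                        schedule=config.schedules.get((r, c)),
                        controller=config.controllers.get((r, c)),
                        dt=dt,
                        noise_prefix=prefix,
                    )
                )
        self._neighbours = self._build_neighbours()
        per_node = list(BeeModel.columns)
        self.columns = tuple(
            f"n{r}_{c}.{col}"
            for r in range(config.n_rows)
            for c in range(config.n_cols)
            for col in per_node
        )

    def _build_neighbours(self) -> list[list[int]]:
        nr, nc = self.config.n_rows, self.config.n_cols
        out: list[list[int]] = []
        for r in range(nr):
            for c in range(nc):
                nbrs = []
                for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc:
                        nbrs.append(rr * nc + cc)
                out.append(nbrs)
        return out

    # -- replicate-runner contract ----------------------------------------
    def begin_run(self, noise: NoiseStream) -> None:
        for node in self.nodes:
            node.begin_run(noise)

    def initial_record(self) -> tuple[float, ...]:
        rec: list[float] = []
        for node in self.nodes:
            rec.extend(node.initial_record())
        return tuple(rec)

    def conserved_total(self) -> float:
        return sum(node.b_r + node.b_l for node in self.nodes)

    def step(self, t: float, dt: float) -> tuple[float, ...]:
        records = [list(node.step(t, dt)) for node in self.nodes]

        d = self.config.d_coupling
        if d > 0.0 and len(self.nodes) > 1:
            # mobile outflow per node and side, from post-step states
            mobile: list[tuple[float, float]] = []
            for node in self.nodes:
                p = node.params
                sch = node.schedule
                tau_r = resting_time(node.t_r, sch.phi_r(t), sch.psi_r(t), p)
                tau_l = resting_time(node.t_l, sch.phi_l(t), sch.psi_l(t), p)
                mobile.append((node.b_r / tau_r, node.b_l / tau_l))
            pops = [(node.b_r, node.b_l) for node in self.nodes]
            delta = [[0.0, 0.0] for _ in self.nodes]
            for i, nbrs in enumerate(self._neighbours):
                for j in nbrs:
                    if j <= i:
                        continue  # handle each pair once, antisymmetrically
                    for s in (0, 1):
                        flow = d * dt * (mobile[i][s] - mobile[j][s])
                        # a donor can send at most a quarter of its side per
                        # neighbour (4-neighbourhood), so it never overdraws
                        if flow > 0.0:
                            flow = min(flow, 0.25 * pops[i][s])
                        else:
                            flow = max(flow, -0.25 * pops[j][s])
                        delta[i][s] -= flow
                        delta[j][s] += flow
            for i, node in enumerate(self.nodes):
                node.b_r = node.b_r + delta[i][0]
                node.b_l = node.b_l + delta[i][1]
                records[i][0] = node.b_r
                records[i][1] = node.b_l

        out: list[float] = []
        for rec in records:
            out.extend(rec)
        return tuple(out)
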