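"""Time evolution: Euler--Maruyama integration, division rounds, stop rules.

A simulation starts from the undivided egg (radius R0 = 1) and proceeds in
stages separated by synchronous division rounds at t = tau_D, 2 tau_D, ...
Each division halves every cell's volume (R_n = R0 / 2^(n/3)); the mother
keeps its position and the second daughter is placed one daughter radius
away along the division axis.  Ordered divisions use +x for the first round
and +y for the second (each round perpendicular to the previous); random
divisions draw the axis uniformly on the sphere, redrawing when the
daughter would substantially overlap a pre-existing cell or land outside
the confining shell.

Stop rules: ``end_of_4cell`` terminates one timestep before the cells at
the final simulated stage would divide again; ``fixed_time`` runs to a set
total time; ``until_topology`` stops at the first contact graph classifying
to a target label (first-passage), capped at T_cap and flagged censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from . import _kernels as K
from .contact_topology import (TopologyLabel, classify_topology,
                               contact_graph_from_arrays, label_code,
                               label_from_code)
from .mechanics import (Cell, ModelParams, ShellPenetrationError, ShellSpec,
                        radius_for_generation)

_ORDERED_AXES = (np.array([1.0, 0.0, 0.0]),
                 np.array([0.0, 1.0, 0.0]),
                 np.array([0.0, 0.0, 1.0]))

# gap (in units of the cell radius) kept between a newly drawn initial cell
# centre and the shell, so the first steps remain within the stable-step
# regime of the divergent shell potential
_INIT_SHELL_GAP_FRAC = 0.5

# ordered-mode mirror fallback threshold: a daughter centre closer than this
# to the shell surface counts as placed into the wall itself (units of R0)
_PLACEMENT_MIN_GAP = 0.02


@dataclass(frozen=True)
class DivisionPlan:
    """Division schedule: mode, inter-division time and number of rounds."""

    mode: Literal["ordered", "random"] = "ordered"
    tauD: float = 10.0
    n_rounds: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("ordered", "random"):
            raise ValueError(f"unknown division mode {self.mode!r}")
        if self.tauD <= 0.0:
            raise ValueError("tauD must be positive")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")


@dataclass(frozen=True)
class StopRule:
    """Termination condition of a run.

    kind = 'end_of_4cell' | 'fixed_time' | 'until_topology'.  ``time`` is
    the total time T for fixed_time runs, or the cap T_cap (measured from
    the birth of the final stage) for until_topology runs.
    """

    kind: Literal["end_of_4cell", "fixed_time", "until_topology"] = "end_of_4cell"
    time: float | None = None
    label: TopologyLabel | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("end_of_4cell", "fixed_time", "until_topology"):
            raise ValueError(f"unknown stop kind {self.kind!r}")
        if self.kind == "fixed_time" and (self.time is None or self.time <= 0):
            raise ValueError("fixed_time requires a positive total time")
        if self.kind == "until_topology":
            if self.label is None:
                raise ValueError("until_topology requires a target label")
            if self.time is None or self.time <= 0:
                raise ValueError("until_topology requires a positive T_cap")


@dataclass(frozen=True)
class SimulationConfig:
    params: ModelParams
    shell: ShellSpec = field(default_factory=ShellSpec)
    plan: DivisionPlan = field(default_factory=DivisionPlan)
    stop: StopRule = field(default_factory=StopRule)
    init: Literal["egg_at_origin", "gaussian"] = "egg_at_origin"
    seed: int = 0
    contact_stride: int = 1
    sample_every: int = 100

    def __post_init__(self) -> None:
        if self.contact_stride < 1 or self.sample_every < 1:
            raise ValueError("contact_stride and sample_every must be >= 1")
        if self.init not in ("egg_at_origin", "gaussian"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.init == "gaussian" and self.shell.kind == "none":
            raise ValueError("gaussian initialization requires a shell")


@dataclass
class Frame:
    """One sampled snapshot of the packing state."""

    time: float
    positions: np.ndarray
    base_radii: np.ndarray
    corrected_radii: np.ndarray
    generations: np.ndarray
    label: TopologyLabel | None


@dataclass
class PackingState:
    """Time-stamped set of cells plus their contact graph and label."""

    time: float
    cells: list[Cell]
    graph: nx.Graph
    label: TopologyLabel | None


@dataclass
class Trajectory:
    frames: list[Frame]
    events: list[dict]
    final_label: TopologyLabel | None
    termination: str
    time_to_target: float | None = None
    censored: bool = False

    @property
    def final_frame(self) -> Frame:
        return self.frames[-1]


def state_from_frame(frame: Frame) -> PackingState:
    cells = [Cell(id=i, position=frame.positions[i].copy(),
                  base_radius=float(frame.base_radii[i]),
                  corrected_radius=float(frame.corrected_radii[i]),
                  generation=int(frame.generations[i]))
             for i in range(len(frame.base_radii))]
    g = contact_graph_from_arrays(frame.positions, frame.base_radii,
                                  frame.corrected_radii)
    label = classify_topology(g) if len(cells) == 4 else None
    return PackingState(time=frame.time, cells=cells, graph=g, label=label)


# ---------------------------------------------------------------------------
# single steps and divisions (API-level operations)

def em_step(state: PackingState, config: SimulationConfig,
            rng: np.random.Generator) -> PackingState:
    """Advance one Euler-Maruyama step and rebuild contacts.

    Library-level convenience around the compiled integrator for a single
    step; production runs use :func:`run_simulation`, which keeps the whole
    loop in compiled code.
    """
    pos = np.array([c.position for c in state.cells], dtype=float)
    base = np.array([c.base_radius for c in state.cells], dtype=float)
    gen = np.array([c.generation for c in state.cells], dtype=int)
    seed = int(rng.integers(0, 2 ** 31 - 1))
    p = config.params
    sh = config.shell
    status, _, Rp, adj, *_ = K.em_run(
        pos, base, np.zeros(len(base), dtype=bool), 1, p.dt, p.sigma_over_U0,
        p.theta, p.alpha, p.beta, p.support_scale_frac, sh.kind_code,
        sh.a_axis, sh.b_axis, sh.A_strength, sh.Us0, 1, -1, 1, seed)
    if status == K.STATUS_PENETRATION:
        raise ShellPenetrationError(
            f"shell penetration at t = {state.time + p.dt:.6g}")
    cells = [Cell(id=c.id, position=pos[i].copy(), base_radius=base[i],
                  corrected_radius=float(Rp[i]), generation=int(gen[i]))
             for i, c in enumerate(state.cells)]
    ids = [c.id for c in cells]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            if adj[i, j]:
                g.add_edge(ids[i], ids[j])
    label = classify_topology(g) if len(cells) == 4 else None
    return PackingState(time=state.time + p.dt, cells=cells, graph=g,
                        label=label)


def divide_all(state: PackingState, plan: DivisionPlan, round_index: int,
               rng: np.random.Generator,
               shell: ShellSpec | None = None) -> PackingState:
    """Simultaneous division of every cell (round ``round_index``, 1-based)."""
    if not (1 <= round_index <= max(plan.n_rounds, round_index)):
        raise ValueError("round_index must be >= 1")
    for c in state.cells:
        if c.generation != round_index - 1:
            raise ValueError(
                f"cell {c.id} has generation {c.generation}, expected {round_index - 1}")
    pos = np.array([c.position for c in state.cells], dtype=float)
    new_pos, new_gen, axes = _divide_arrays(
        pos, round_index, plan.mode, rng, shell)
    rn = radius_for_generation(round_index)
    cells = [Cell(id=i, position=new_pos[i].copy(), base_radius=rn,
                  corrected_radius=rn, generation=int(new_gen[i]))
             for i in range(len(new_pos))]
    g = contact_graph_from_arrays(new_pos, np.full(len(new_pos), rn))
    label = classify_topology(g) if len(cells) == 4 else None
    return PackingState(time=state.time, cells=cells, graph=g, label=label)


def _divide_arrays(pos: np.ndarray, round_index: int, mode: str,
                   rng: np.random.Generator,
                   shell: ShellSpec | None):
    """Division on raw position arrays; returns (positions, generations,
    per-mother division axes)."""
    n_mothers = pos.shape[0]
    rn = radius_for_generation(round_index)
    new_pos = np.empty((2 * n_mothers, 3))
    new_pos[:n_mothers] = pos  # mothers keep their positions (daughter 1)
    axes = np.empty((n_mothers, 3))
    for m in range(n_mothers):
        if mode == "ordered":
            axis = _ORDERED_AXES[(round_index - 1) % 3]
            daughter = pos[m] + rn * axis
            if shell is not None and shell.kind != "none":
                # the rule fixes the division axis, not its sign: fall back
                # to the mirrored position when the + side would put the
                # daughter centre on or through the shell wall itself
                gap = K.shell_gap(daughter[0], daughter[1], daughter[2],
                                  shell.a_axis, shell.b_axis)
                if gap < _PLACEMENT_MIN_GAP:
                    alt = pos[m] - rn * axis
                    alt_gap = K.shell_gap(alt[0], alt[1], alt[2],
                                          shell.a_axis, shell.b_axis)
                    if alt_gap > gap:
                        daughter = alt
                        axis = -axis
        else:
            daughter = None
            for _ in range(100):
                axis = _random_unit_vector(rng)
                cand = pos[m] + rn * axis
                ok = True
                # reject substantial overlap with any pre-existing cell
                # other than the mother (all cells now have radius rn)
                for k in range(n_mothers):
                    if k == m:
                        continue
                    if np.linalg.norm(cand - pos[k]) < 0.5 * (rn + rn):
                        ok = False
                        break
                if ok and shell is not None and shell.kind != "none":
                    # keep at least half a daughter radius of physical gap
                    # to the shell; closer starts sit in the divergent
                    # boundary layer and overshoot through the shell
                    gap = K.shell_gap(cand[0], cand[1], cand[2],
                                      shell.a_axis, shell.b_axis)
                    if gap < _INIT_SHELL_GAP_FRAC * rn:
                        ok = False
                if ok:
                    daughter = cand
                    break
            if daughter is None:
                raise RuntimeError(
                    f"could not place daughter of cell {m} after 100 attempts "
                    "(crowded configuration)")
        new_pos[n_mothers + m] = daughter
        axes[m] = axis
    gens = np.full(2 * n_mothers, round_index, dtype=int)
    return new_pos, gens, axes


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# full runs

def _initial_position(config: SimulationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    if config.init == "egg_at_origin":
        return np.zeros(3)
    # Gaussian initial position, per-component variance b/10, truncated so
    # that the egg centre keeps a physical gap of at least half its radius
    # to the shell (the divergent boundary makes closer starts unstable at
    # the fixed timestep)
    sh = config.shell
    sd = np.sqrt(sh.b_axis / 10.0)
    for _ in range(1000):
        p = rng.normal(scale=sd, size=3)
        if K.shell_gap(p[0], p[1], p[2], sh.a_axis,
                       sh.b_axis) >= _INIT_SHELL_GAP_FRAC * 1.0:
            return p
    raise RuntimeError("could not draw an initial egg position inside the shell")


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run one seeded trajectory according to the config's stop rule."""
    p = config.params
    sh = config.shell
    plan = config.plan
    dt = p.dt
    steps_per_stage = int(round(plan.tauD / dt))
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = ss.generate_state(plan.n_rounds + 2).astype(np.int64) % (2 ** 31)
    div_rng = np.random.default_rng(ss.spawn(1)[0])

    pos = _initial_position(config, div_rng)[None, :].copy()
    base = np.array([1.0])
    gen = np.array([0])
    frames: list[Frame] = []
    events: list[dict] = []
    t_offset = 0.0

    def _run_stage(n_steps, target, stage_idx, final):
        nonlocal pos, t_offset
        frozen = np.zeros(len(base), dtype=bool)
        status, stop_step, Rp, adj, ns, t_buf, pos_buf, rp_buf, lab_buf = K.em_run(
            pos, base, frozen, n_steps, dt, p.sigma_over_U0, p.theta, p.alpha,
            p.beta, p.support_scale_frac, sh.kind_code, sh.a_axis, sh.b_axis,
            sh.A_strength, sh.Us0, config.contact_stride, target,
            config.sample_every, int(stage_seeds[stage_idx]))
        for k in range(ns):
            lab = (label_from_code(lab_buf[k])
                   if len(base) == 4 and lab_buf[k] >= 0 else None)
            frames.append(Frame(time=t_offset + t_buf[k],
                                positions=pos_buf[k].copy(),
                                base_radii=base.copy(),
                                corrected_radii=rp_buf[k].copy(),
                                generations=gen.copy(), label=lab))
        if status == K.STATUS_PENETRATION:
            raise ShellPenetrationError(
                f"shell penetration at t = {t_offset + stop_step * dt:.6g} "
                f"(stage {stage_idx}, step {stop_step}, seed {config.seed})")
        t_offset += stop_step * dt if status == K.STATUS_TARGET else n_steps * dt
        return status, stop_step

    # division stages 0 .. n_rounds-1
    for stage in range(plan.n_rounds):
        _run_stage(steps_per_stage, -1, stage, final=False)
        new_pos, new_gen, axes = _divide_arrays(
            pos, stage + 1, plan.mode, div_rng, sh)
        for m in range(pos.shape[0]):
            events.append({"time": t_offset, "round": stage + 1, "mother": m,
                           "daughter": pos.shape[0] + m,
                           "axis": [float(a) for a in axes[m]]})
        pos = new_pos
        gen = new_gen
        base = np.full(len(pos), radius_for_generation(stage + 1))

    birth_time = t_offset  # birth of the final (4-cell) stage

    stop = config.stop
    time_to_target = None
    censored = False
    if stop.kind == "end_of_4cell":
        n_final = steps_per_stage - 1
        _run_stage(n_final, -1, plan.n_rounds, final=True)
        termination = "end_of_stage"
    elif stop.kind == "fixed_time":
        n_total = int(round(stop.time / dt))
        n_final = max(n_total - plan.n_rounds * steps_per_stage, 0)
        _run_stage(n_final, -1, plan.n_rounds, final=True)
        termination = "fixed_time"
    else:  # until_topology
        n_cap = int(round(stop.time / dt))
        target = label_code(stop.label)
        status, stop_step = _run_stage(n_cap, target, plan.n_rounds, final=True)
        if status == K.STATUS_TARGET:
            time_to_target = stop_step * dt
            termination = "target_reached"
        else:
            time_to_target = stop.time
            censored = True
            termination = "censored"

    final = frames[-1]
    final_label = final.label if len(final.base_radii) == 4 else None
    return Trajectory(frames=frames, events=events, final_label=final_label,
                      termination=termination, time_to_target=time_to_target,
                      censored=censored)


def relax_from_state(positions: np.ndarray, base_radii: np.ndarray,
                     params: ModelParams, shell: ShellSpec,
                     target: TopologyLabel | None, t_max: float, seed: int,
                     contact_stride: int = 1, sample_every: int = 100,
                     frozen: np.ndarray | None = None):
    """Advance an arbitrary cell configuration without divisions.

    Returns (status, time, positions, sampled times, sampled positions,
    sampled label codes).  Used for relaxation from fixtures and for the
    angular-MSD assay (via ``frozen``).
    """
    pos = np.array(positions, dtype=float)
    base = np.asarray(base_radii, dtype=float)
    if frozen is None:
        frozen = np.zeros(len(base), dtype=bool)
    p = params
    n_steps = int(round(t_max / p.dt))
    tcode = label_code(target) if target is not None else -1
    status, stop_step, Rp, adj, ns, t_buf, pos_buf, rp_buf, lab_buf = K.em_run(
        pos, base, frozen, n_steps, p.dt, p.sigma_over_U0, p.theta, p.alpha,
        p.beta, p.support_scale_frac, shell.kind_code, shell.a_axis,
        shell.b_axis, shell.A_strength, shell.Us0, contact_stride, tcode,
        sample_every, seed % (2 ** 31))
    if status == K.STATUS_PENETRATION:
        raise ShellPenetrationError(
            f"shell penetration at t = {stop_step * p.dt:.6g} (seed {seed})")
    t = stop_step * p.dt if status == K.STATUS_TARGET else n_steps * p.dt
    return status, t, pos, t_buf[:ns].copy(), pos_buf[:ns].copy(), lab_buf[:ns].copy()
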