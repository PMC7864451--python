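"""Measurement campaigns on the 4-cell packing model.

Four assays: packing-frequency tables over parameter grids (final topology
of end-of-4-cell-stage runs), first-passage times to the equilibrium
tetrahedral packing, topology time courses along the relaxation (time
rescaled per run by its own equilibration time t_E), and the angular
mean-squared displacement of one blastomere diffusing over the potential
rim of three immobilized blastomeres.

All assays derive per-run seeds deterministically from a single base seed
via ``numpy.random.SeedSequence`` spawning, so any table is bit-reproducible
from (config, n_runs, seed_base).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .contact_topology import TopologyLabel
from .dynamics import (SimulationConfig, StopRule, relax_from_state,
                       run_simulation)
from .mechanics import ModelParams, ShellSpec, equilibrium_distance, \
    radius_for_generation

LABELS = [lab.value for lab in TopologyLabel]


def child_seeds(seed_base: int, n: int) -> np.ndarray:
    """Deterministic per-run seeds (< 2^31) spawned from one base seed."""
    return (np.random.SeedSequence(seed_base).generate_state(n).astype(np.int64)
            % (2 ** 31))


# ---------------------------------------------------------------------------
# packing frequencies

def packing_frequency(config_grid: Sequence[SimulationConfig], n_runs: int,
                      seed_base: int = 0) -> pd.DataFrame:
    """Final-topology frequency table over a grid of configurations.

    Runs ``n_runs`` independently seeded simulations per grid point with the
    end-of-4-cell-stage stop rule and tabulates the final contact-graph
    labels.  Returns one row per grid point with counts and frequencies per
    label (frequencies sum to 1 by construction).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for g_idx, cfg in enumerate(config_grid):
        cfg = dc_replace(cfg, stop=StopRule(kind="end_of_4cell"))
        seeds = child_seeds(seed_base + g_idx, n_runs)
        counts = {lab: 0 for lab in LABELS}
        for seed in seeds:
            traj = run_simulation(dc_replace(cfg, seed=int(seed)))
            counts[traj.final_label.value] += 1
        row = {
            "theta": cfg.params.theta,
            "tauD_over_tauM": cfg.plan.tauD,
            "division_mode": cfg.plan.mode,
            "shell_kind": cfg.shell.kind,
            "a_axis": cfg.shell.a_axis,
            "b_axis": cfg.shell.b_axis,
            "Us0_over_U0": cfg.shell.Us0,
            "n_runs": n_runs,
            "seed_base": seed_base + g_idx,
        }
        for lab in LABELS:
            row[f"count_{lab}"] = counts[lab]
            row[f"freq_{lab}"] = counts[lab] / n_runs
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# relaxation times

@dataclass
class RelaxationResult:
    """Per-run first-passage times (units tau_M) from the birth of the
    4-cell stage to the first classification as the target label."""

    times: np.ndarray
    censored: np.ndarray
    T_cap: float
    target: TopologyLabel
    seed_base: int

    @property
    def median(self) -> float:
        return float(np.median(self.times))

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"run": np.arange(len(self.times)),
                             "time": self.times, "censored": self.censored})


def time_to_equilibrium(config: SimulationConfig, n_runs: int, T_cap: float,
                        seed_base: int = 0,
                        target: TopologyLabel = TopologyLabel.TETRAHEDRON,
                        ) -> RelaxationResult:
    """First-passage time to the target topology over seeded replicates.

    The clock starts at the second division (birth of the 4-cell stage);
    runs that do not reach the target within T_cap carry time = T_cap and
    are flagged censored (never dropped silently).
    """
    cfg = dc_replace(config, stop=StopRule(kind="until_topology", time=T_cap,
                                           label=target))
    seeds = child_seeds(seed_base, n_runs)
    times = np.empty(n_runs)
    cens = np.zeros(n_runs, dtype=bool)
    for k, seed in enumerate(seeds):
        traj = run_simulation(dc_replace(cfg, seed=int(seed)))
        times[k] = traj.time_to_target
        cens[k] = traj.censored
    if cens.all():
        # still returned, but callers should know nothing equilibrated
        pass
    return RelaxationResult(times=times, censored=cens, T_cap=T_cap,
                            target=target, seed_base=seed_base)


# ---------------------------------------------------------------------------
# topology time course

def topology_time_course(config: SimulationConfig, n_runs: int,
                         n_timebins: int = 20, T_cap: float = 1e4,
                         seed_base: int = 0,
                         target: TopologyLabel = TopologyLabel.TETRAHEDRON,
                         ) -> pd.DataFrame:
    """Label frequencies during relaxation, on time rescaled to [0, 1] by
    each run's own equilibration time t_E; censored runs are excluded.

    Returns a DataFrame with one row per bin: bin centre t/t_E and the
    frequency of each label among the uncensored runs (rows sum to 1).
    """
    cfg = dc_replace(config, stop=StopRule(kind="until_topology", time=T_cap,
                                           label=target))
    seeds = child_seeds(seed_base, n_runs)
    # evaluate each bin at its right edge so the final bin sits exactly at
    # t = t_E, where the label is the target by construction
    edges = np.linspace(0.0, 1.0, n_timebins + 1)[1:]
    counts = np.zeros((n_timebins, len(LABELS)), dtype=int)
    n_used = 0
    for seed in seeds:
        traj = run_simulation(dc_replace(cfg, seed=int(seed)))
        if traj.censored:
            continue
        t_E = traj.time_to_target
        # frames of the 4-cell stage only
        stage = [f for f in traj.frames if len(f.base_radii) == 4]
        t0 = stage[0].time
        ts = np.array([f.time - t0 for f in stage])
        labs = [f.label for f in stage]
        if t_E <= 0.0:
            counts[:, LABELS.index(target.value)] += 1
            n_used += 1
            continue
        for b, tc in enumerate(edges):
            # epsilon guards one-ulp mismatches between frame times and t_E
            idx = int(np.searchsorted(ts, tc * t_E + 1e-9, side="right")) - 1
            idx = max(idx, 0)
            lab = labs[idx]
            counts[b, LABELS.index(lab.value)] += 1
        n_used += 1
    if n_used == 0:
        raise RuntimeError("no uncensored runs: cannot build a time course")
    out = pd.DataFrame(counts / n_used, columns=[f"freq_{l}" for l in LABELS])
    out.insert(0, "t_over_tE", edges)
    out["n_runs_used"] = n_used
    return out


# ---------------------------------------------------------------------------
# angular mean squared displacement

@dataclass
class AngularTrace:
    """Angular MSD of a mobile blastomere over three immobilized ones.

    ``theta_t`` holds the sampled elevation angle per run (n_runs x n_t);
    ``msd`` is the time-and-ensemble averaged squared angular displacement
    at the lag times in ``t``; ``slope``
    is the log-log slope fitted on the diffusive window and ``D_fit`` the
    corresponding angular diffusion coefficient from MSD = 2 D t.
    """

    t: np.ndarray
    theta_t: np.ndarray
    msd: np.ndarray
    slope: float
    D_fit: float
    n_runs: int


def angular_msd(params: ModelParams, n_runs: int = 8, t_max: float = 2000.0,
                seed_base: int = 0, sample_every: int = 200,
                fit_window: tuple[float, float] | None = None,
                contact_stride: int = 20) -> AngularTrace:
    """Angular MSD assay for the floppy rotational mode.

    Three cells of 4-cell-stage radius R2 = 2^(-2/3) are immobilized at the
    vertices of an equilateral triangle in the x-y plane with pairwise
    separation r* (centroid at the origin); a fourth, mobile cell starts on
    the triangle's rim at zero elevation, at distance r* from the two
    nearest cells.  theta(t) is the elevation angle of the mobile cell
    relative to the x-y plane through the centroid; the MSD is the time-
    and-ensemble averaged squared angular displacement over lag times, and
    the log-log slope is fitted over ``fit_window`` (in tau_M; defaults to
    [5, t_max/4], where each lag estimate still averages many sliding
    origins).
    """
    if fit_window is None:
        fit_window = (5.0, t_max / 4.0)
    R = radius_for_generation(2)
    rstar = equilibrium_distance(R, R, params.theta)
    rho = rstar / np.sqrt(3.0)  # triangle circumradius
    ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                    np.pi / 2 + 4 * np.pi / 3])
    fixed = np.stack([rho * np.cos(ang), rho * np.sin(ang),
                      np.zeros(3)], axis=1)
    # rim start: outward through the midpoint of the edge between cells 1, 2
    mid = 0.5 * (fixed[1] + fixed[2])
    u = mid / np.linalg.norm(mid)
    start = u * (np.linalg.norm(mid) + np.sqrt(3.0) * rstar / 2.0)
    base = np.full(4, R)
    frozen = np.array([True, True, True, False])
    shell = ShellSpec()
    seeds = child_seeds(seed_base, n_runs)
    thetas = []
    for seed in seeds:
        pos0 = np.vstack([fixed, start[None, :]])
        _, _, _, t_s, pos_s, _ = relax_from_state(
            pos0, base, params, shell, None, t_max, int(seed),
            contact_stride=contact_stride, sample_every=sample_every,
            frozen=frozen)
        p = pos_s[:, 3, :]
        r = np.linalg.norm(p, axis=1)
        thetas.append(np.arcsin(np.clip(p[:, 2] / r, -1.0, 1.0)))
    n_t = min(len(th) for th in thetas)
    theta_t = np.stack([th[:n_t] for th in thetas])
    t = t_s[:n_t]
    # time-and-ensemble averaged MSD over lag times: the angular random walk
    # has stationary increments, so averaging over sliding origins gives a
    # far less noisy estimate than the fixed-origin average at small n_runs;
    # evaluated on ~400 log-spaced lags to keep the cost linear
    if n_t > 400:
        lags = np.unique(np.concatenate(
            [[0, 1], np.geomspace(1, n_t - 1, 400).astype(int)]))
    else:
        lags = np.arange(n_t)
    msd = np.empty(len(lags))
    for q, lag in enumerate(lags):
        if lag == 0:
            msd[q] = 0.0
        else:
            diffs = theta_t[:, lag:] - theta_t[:, :-lag]
            msd[q] = np.mean(diffs ** 2)
    t = t[lags]
    lo, hi = fit_window
    mask = (t >= lo) & (t <= hi) & (msd > 0.0)
    slope, intercept = np.polyfit(np.log(t[mask]), np.log(msd[mask]), 1)
    D_fit = float(np.exp(intercept) / 2.0)
    return AngularTrace(t=t, theta_t=theta_t, msd=msd, slope=float(slope),
                        D_fit=D_fit, n_runs=n_runs)
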