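"""Potentials, forces and geometric quantities of the blastomere model.

Each blastomere is a particle of radius ``R`` interacting with its contact
neighbours through a short-ranged potential with a repulsive core (volume
exclusion) and an attractive well (adhesion), and optionally with a rigid
axisymmetric ellipsoidal shell that is either purely repulsive or sticky.
Everything is expressed in normalized units: lengths in units of the egg
radius R0 = 1, energies in units of the cell-cell adhesion scale U0 = 1,
friction mu = 1, so the mechanical relaxation time tau_M = mu R0^2/U0 = 1
is the unit of time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K


class ShellPenetrationError(RuntimeError):
    """A cell centre reached or crossed the confining shell (level >= 1)."""


@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical parameters of the cell-cell interaction.

    Parameters
    ----------
    theta:
        Contact angle between cells, radians, in [0, pi/2).  Encodes the
        adhesion / cortical-tension balance and fixes the equilibrium pair
        distance r* = (Ri+Rj) cos(theta).
    alpha, beta:
        Exponents of the repulsive and attractive branches (alpha > beta).
    support_scale_frac:
        The support-function decay length is a = support_scale_frac*(Ri+Rj);
        small values give a sharp, still differentiable cutoff.
    sigma_over_U0:
        Magnitude of the random force fluctuations relative to U0.
    dt:
        Integration timestep in units of tau_M.
    """

    theta: float
    alpha: float = 4.0
    beta: float = 3.0
    support_scale_frac: float = 0.01
    sigma_over_U0: float = 5e-5
    dt: float = 1e-3
    U0: float = field(default=1.0, repr=False)
    mu: float = field(default=1.0, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < np.pi / 2):
            raise ValueError(f"theta must lie in [0, pi/2), got {self.theta}")
        if not (self.alpha > self.beta > 0.0):
            raise ValueError(
                f"alpha > beta > 0 required, got alpha={self.alpha}, beta={self.beta}")
        if self.support_scale_frac <= 0.0:
            raise ValueError("support_scale_frac must be positive")
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.sigma_over_U0 < 0.0:
            raise ValueError("sigma_over_U0 must be non-negative")


@dataclass
class Cell:
    """One blastomere.

    ``base_radius`` follows the cleavage law R_n = R0 / 2^(n/3) for
    generation n (total volume conservation across divisions);
    ``corrected_radius`` is the per-step volume-corrected radius R' >= R
    that absorbs the overlap volume with contacting neighbours.
    """

    id: int
    position: np.ndarray
    base_radius: float
    corrected_radius: float = 0.0
    generation: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.base_radius <= 0.0:
            raise ValueError("base_radius must be positive")
        if self.corrected_radius == 0.0:
            self.corrected_radius = self.base_radius
        if self.corrected_radius < self.base_radius:
            raise ValueError("corrected_radius must be >= base_radius")


def radius_for_generation(n: int, R0: float = 1.0) -> float:
    """Cleavage radius law R_n = R0 / 2^(n/3)."""
    return R0 * 2.0 ** (-n / 3.0)


_SHELL_KINDS = {"none": K.SHELL_NONE,
                "repulsive": K.SHELL_REPULSIVE,
                "sticky": K.SHELL_STICKY}


@dataclass(frozen=True)
class ShellSpec:
    """Confining shell: kind and axisymmetric ellipsoid geometry.

    ``a_axis`` is the major semi-axis (x direction), ``b_axis`` the minor
    semi-axis (y and z); a sphere has a_axis == b_axis.  ``A_strength`` is
    the repulsive energy scale (units of U0) and ``Us0`` the sticky
    adhesion energy scale.
    """

    kind: str = "none"
    a_axis: float = 0.0
    b_axis: float = 0.0
    A_strength: float = 10.0
    Us0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _SHELL_KINDS:
            raise ValueError(f"unknown shell kind {self.kind!r}")
        if self.kind != "none":
            if not (self.a_axis >= self.b_axis > 0.0):
                raise ValueError("require a_axis >= b_axis > 0")
            if self.A_strength <= 0.0:
                raise ValueError("A_strength must be positive")
            if self.Us0 < 0.0:
                raise ValueError("Us0 must be non-negative")
            if self.kind == "sticky" and self.Us0 <= 0.0:
                raise ValueError("sticky shell requires Us0 > 0")

    @property
    def kind_code(self) -> int:
        return _SHELL_KINDS[self.kind]

    @property
    def volume(self) -> float:
        return 4.0 * np.pi * self.a_axis * self.b_axis ** 2 / 3.0

    @classmethod
    def from_volume_ratio(cls, kind: str, Vs_over_Vc: float, aspect: float = 1.0,
                          R0: float = 1.0, A_strength: float = 10.0,
                          Us0: float = 0.0) -> "ShellSpec":
        a_ax, b_ax = shell_axes_from_ratio(Vs_over_Vc, aspect, R0)
        return cls(kind=kind, a_axis=a_ax, b_axis=b_ax,
                   A_strength=A_strength, Us0=Us0)


# ---------------------------------------------------------------------------
# cell-cell interaction

def equilibrium_distance(Ri: float, Rj: float, theta: float) -> float:
    """Equilibrium pair distance r*_ij = (Ri + Rj) cos(theta)."""
    if Ri <= 0.0 or Rj <= 0.0:
        raise ValueError("radii must be positive")
    if not (0.0 <= theta < np.pi / 2):
        raise ValueError("theta must lie in [0, pi/2)")
    return (Ri + Rj) * np.cos(theta)


def cell_cell_potential(rij: float, Ri: float, Rj: float,
                        params: ModelParams) -> float:
    """Pair interaction energy U_c(r); minimum -U0 at r*_ij, ~0 beyond Ri+Rj."""
    if rij <= 0.0:
        raise ValueError("rij must be positive")
    return float(K.pair_potential(rij, Ri, Rj, params.theta, params.alpha,
                                  params.beta, params.support_scale_frac))


def cell_cell_force(pos_i: np.ndarray, pos_j: np.ndarray, Ri: float, Rj: float,
                    params: ModelParams) -> np.ndarray:
    """Force -dU_c/dr * rhat on cell i from cell j (antisymmetric in i<->j)."""
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    d = pos_i - pos_j
    r = float(np.linalg.norm(d))
    if r == 0.0:
        raise ValueError("coincident cell positions")
    du = K.pair_dudr(r, Ri, Rj, params.theta, params.alpha, params.beta,
                     params.support_scale_frac)
    return -du * d / r


# ---------------------------------------------------------------------------
# confining shell

def ellipsoid_level(pos: np.ndarray, shell: ShellSpec) -> float:
    """Level-set value c = x^2/a^2 + (y^2+z^2)/b^2 (c = 1 on the shell)."""
    if shell.kind == "none":
        raise ValueError("no shell present")
    x, y, z = np.asarray(pos, dtype=float)
    return float(K.ellipsoid_level(x, y, z, shell.a_axis, shell.b_axis))


def repulsive_shell_potential(pos: np.ndarray, R: float,
                              shell: ShellSpec) -> float:
    """U_s = A/(1 - sqrt(c)) once within reach of the shell, else 0."""
    if shell.kind != "repulsive":
        raise ValueError("shell is not repulsive")
    c = ellipsoid_level(pos, shell)
    if np.sqrt(c) >= 1.0:
        raise ShellPenetrationError(
            f"cell centre on/outside the shell (level {c:.6g})")
    x, y, z = np.asarray(pos, dtype=float)
    return float(K.shell_potential(x, y, z, R, 0.0, K.SHELL_REPULSIVE,
                                   shell.a_axis, shell.b_axis,
                                   shell.A_strength, 0.0, 4.0, 3.0))


def sticky_shell_potential(pos: np.ndarray, cell: Cell, shell: ShellSpec,
                           params: ModelParams) -> float:
    """Adhesive shell well with equilibrium gap r_i* = R_i cos(theta), depth
    -Us0, written in the physical gap length b(1 - sqrt(c)) (exactly b - r
    for a spherical shell)."""
    if shell.kind != "sticky":
        raise ValueError("shell is not sticky")
    c = ellipsoid_level(pos, shell)
    if np.sqrt(c) >= 1.0:
        raise ShellPenetrationError(
            f"cell centre on/outside the shell (level {c:.6g})")
    x, y, z = np.asarray(pos, dtype=float)
    return float(K.shell_potential(x, y, z, cell.base_radius, params.theta,
                                   K.SHELL_STICKY, shell.a_axis, shell.b_axis,
                                   shell.A_strength, shell.Us0,
                                   params.alpha, params.beta))


def shell_force(pos: np.ndarray, cell: Cell, shell: ShellSpec,
                params: ModelParams) -> np.ndarray:
    """Analytic force -grad U_s of the active shell potential."""
    if shell.kind == "none":
        raise ValueError("no shell present")
    c = ellipsoid_level(pos, shell)
    if np.sqrt(c) >= 1.0:
        raise ShellPenetrationError(
            f"cell centre on/outside the shell (level {c:.6g})")
    x, y, z = np.asarray(pos, dtype=float)
    out = np.empty(3)
    K.shell_force(x, y, z, cell.base_radius, params.theta, shell.kind_code,
                  shell.a_axis, shell.b_axis, shell.A_strength, shell.Us0,
                  params.alpha, params.beta, out)
    return out


def shell_axes_from_ratio(Vs_over_Vc: float, aspect: float,
                          R0: float = 1.0) -> tuple[float, float]:
    """Semi-axes (a, b) of an axisymmetric ellipsoid with volume
    Vs = Vs_over_Vc * (4 pi R0^3 / 3) and aspect ratio a/b."""
    if Vs_over_Vc <= 0.0 or R0 <= 0.0:
        raise ValueError("volume ratio and R0 must be positive")
    if aspect < 1.0:
        raise ValueError("aspect ratio a/b must be >= 1")
    b = (Vs_over_Vc / aspect) ** (1.0 / 3.0) * R0
    return aspect * b, b


# ---------------------------------------------------------------------------
# volume correction

def sphere_overlap_volume(d: float, Ri: float, Rj: float) -> float:
    """Lens volume of two intersecting spheres (clamped to containment)."""
    if d < 0.0 or Ri <= 0.0 or Rj <= 0.0:
        raise ValueError("need d >= 0 and positive radii")
    return float(K.lens_volume(d, Ri, Rj))


def corrected_radius(Ri: float, Vo_total: float) -> float:
    """R' from 4/3 pi R'^3 = 4/3 pi Ri^3 + Vo_total."""
    if Vo_total < 0.0:
        raise ValueError("overlap volume must be non-negative")
    return float((Ri ** 3 + 0.75 * Vo_total / np.pi) ** (1.0 / 3.0))


def self_consistent_pair_distance(R: float, theta: float,
                                  tol: float = 1e-12) -> float:
    """Stationary separation of an equal pair under the volume correction.

    The interaction is parameterized by the corrected radii R', which in
    turn depend on the pair overlap at the current separation, so the
    noise-free rest distance is the fixed point of
    r = 2 R'(r) cos(theta) with R'(r) = corrected_radius(R, lens(r, R, R)).
    Converges in a few iterations (the map is a strong contraction).
    """
    r = 2.0 * R * np.cos(theta)
    for _ in range(200):
        rp = corrected_radius(R, sphere_overlap_volume(r, R, R))
        r_new = 2.0 * rp * np.cos(theta)
        if abs(r_new - r) < tol:
            return float(r_new)
        r = r_new
    return float(r)
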