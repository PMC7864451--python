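"""Numba-compiled numerical core.

Everything that runs inside the Euler--Maruyama time loop lives here, as
scalar/array functions with no Python objects: the cell--cell pair potential
and its analytic derivative, the repulsive and sticky shell potentials and
forces, the lens (sphere--sphere intersection) volume used by the per-step
volume correction, the weighted-Voronoi face test that decides which cells
are in contact, the 4-node topology classifier, and the integrator itself.

All quantities are in normalized units: lengths in units of the egg radius
R0, energies in units of the cell--cell adhesion scale U0, times in units of
the mechanical relaxation time tau_M = mu R0^2 / U0 (mu = 1).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# geometry constants

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

def _dodecahedron_normals() -> np.ndarray:
    """Unit face normals of a regular dodecahedron in a fixed canonical
    orientation (the standard (0, +-1, +-phi) cyclic construction)."""
    raw = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            raw.append((0.0, s1, s2 * _PHI))
            raw.append((s1, s2 * _PHI, 0.0))
            raw.append((s1 * _PHI, 0.0, s2))
    normals = np.asarray(raw)
    return normals / np.sqrt(1.0 + _PHI * _PHI)

DODEC_NORMALS = _dodecahedron_normals()

# circumradius / inradius ratio of the regular dodecahedron
DODEC_CIRC_OVER_IN = float(np.sqrt(3.0) * np.tan(np.pi / 5.0))

# face area below which a Voronoi face is treated as absent (ties broken
# toward "no contact"); in units of R0^2
EPS_FACE_AREA = 1e-10

# topology label codes for 4-cell adjacency graphs
LAB_LINE = 0
LAB_T_SHAPE = 1
LAB_SQUARE = 2
LAB_DIAMOND = 3
LAB_TETRAHEDRON = 4
LAB_OTHER = 5

# shell kind codes
SHELL_NONE = 0
SHELL_REPULSIVE = 1
SHELL_STICKY = 2

# run status codes
STATUS_COMPLETED = 0
STATUS_TARGET = 1
STATUS_PENETRATION = 2

# largest admissible deterministic displacement per (sub)step, units of R0;
# an update that would move a cell further is advanced in shorter partial
# steps (forces refreshed each time) so the stiff divergent shell core is
# integrated stably through post-division transients
MAX_STEP_DISP = 0.02
MAX_SUBSTEPS = 1000000


# ---------------------------------------------------------------------------
# cell-cell interaction

@njit(cache=True)
def pair_potential(r, Ri, Rj, theta, alpha, beta, afrac):
    """Cell-cell interaction energy U_c(r) in units of U0.

    A Mie-type attractive/repulsive potential multiplied by a smooth
    support function S(r) = 1/(1+f(r)), f(r) = exp((r - (Ri+Rj))/a) with
    a = afrac*(Ri+Rj), which switches the interaction off beyond the cell
    size Ri+Rj.  The coefficients are fixed so that the global minimum is
    exactly -U0 at the equilibrium distance r* = (Ri+Rj) cos(theta).
    """
    rsum = Ri + Rj
    a = afrac * rsum
    rstar = rsum * np.cos(theta)
    fstar = np.exp((rstar - rsum) / a)
    ca = rstar ** alpha * (beta + fstar * (beta + rstar / a))
    cb = rstar ** beta * (alpha + fstar * (alpha + rstar / a))
    x = (r - rsum) / a
    if x > 600.0:
        x = 600.0
    f = np.exp(x)
    s = 1.0 / (1.0 + f)
    g = ca / r ** alpha - cb / r ** beta
    return s * g / (alpha - beta)


@njit(cache=True)
def pair_dudr(r, Ri, Rj, theta, alpha, beta, afrac):
    """Radial derivative dU_c/dr of the pair potential (units U0/R0)."""
    rsum = Ri + Rj
    a = afrac * rsum
    rstar = rsum * np.cos(theta)
    fstar = np.exp((rstar - rsum) / a)
    ca = rstar ** alpha * (beta + fstar * (beta + rstar / a))
    cb = rstar ** beta * (alpha + fstar * (alpha + rstar / a))
    x = (r - rsum) / a
    if x > 600.0:
        x = 600.0
    f = np.exp(x)
    s = 1.0 / (1.0 + f)
    g = ca / r ** alpha - cb / r ** beta
    ds = -(f / a) * s * s
    dg = -alpha * ca / r ** (alpha + 1.0) + beta * cb / r ** (beta + 1.0)
    return (ds * g + s * dg) / (alpha - beta)


# ---------------------------------------------------------------------------
# confining shell

@njit(cache=True)
def ellipsoid_level(x, y, z, a_ax, b_ax):
    """Level-set value c = x^2/a^2 + (y^2+z^2)/b^2; c = 1 on the shell."""
    return x * x / (a_ax * a_ax) + (y * y + z * z) / (b_ax * b_ax)


@njit(cache=True)
def shell_gap(x, y, z, a_ax, b_ax):
    """Local physical distance from a point to the shell surface,
    s = (1 - sqrt(c)) / |grad sqrt(c)|.

    Exact for spheres (s = b - r) and first-order accurate for ellipsoids:
    the level gap (1 - sqrt(c)) alone is not a length and badly
    overestimates proximity along the major axis of elongated shells.
    Returns a large sentinel at the centre where grad sqrt(c) vanishes.
    """
    c = ellipsoid_level(x, y, z, a_ax, b_ax)
    sq = np.sqrt(c)
    if sq < 1e-12:
        return b_ax  # centre: distance is b (minor axis) or more
    gx = x / (a_ax * a_ax * sq)
    gy = y / (b_ax * b_ax * sq)
    gz = z / (b_ax * b_ax * sq)
    gnorm = np.sqrt(gx * gx + gy * gy + gz * gz)
    return (1.0 - sq) / gnorm


@njit(cache=True)
def shell_potential(x, y, z, R, theta, kind, a_ax, b_ax, A, Us0, alpha, beta):
    """Shell interaction energy of a cell of radius R at (x, y, z).

    Both potentials are written in the local physical gap s to the shell
    and are active while the shell is within the cell's reach (s <= R; the
    Heaviside boundary itself counts as active).  Repulsive shell: A/s,
    diverging at the wall.  Sticky shell: a Mie-type well in s with
    equilibrium gap r_i* = R cos(theta) and depth -Us0.
    """
    if kind == SHELL_NONE:
        return 0.0
    s = shell_gap(x, y, z, a_ax, b_ax)
    if s > R:
        return 0.0
    if kind == SHELL_REPULSIVE:
        return A / s
    ristar = R * np.cos(theta)
    return (beta * ristar ** alpha / s ** alpha
            - alpha * ristar ** beta / s ** beta) * Us0 / (alpha - beta)


@njit(cache=True)
def shell_force(x, y, z, R, theta, kind, a_ax, b_ax, A, Us0, alpha, beta, out):
    """Analytic shell force -grad U_s on a cell of radius R; fills out[0:3].

    The gap gradient is taken along the local outward normal (grad sqrt(c)
    direction); the curvature correction from the slowly varying normal is
    second order and neglected.
    """
    out[0] = 0.0
    out[1] = 0.0
    out[2] = 0.0
    if kind == SHELL_NONE:
        return
    c = ellipsoid_level(x, y, z, a_ax, b_ax)
    sq = np.sqrt(c)
    if sq < 1e-12:
        # grad sqrt(c) singular at the centre; by symmetry no force there
        return
    s = shell_gap(x, y, z, a_ax, b_ax)
    if s > R:
        return
    if -1e-12 < s < 1e-12:
        s = 1e-12  # on the wall itself; the run aborts at the level check
    if kind == SHELL_REPULSIVE:
        duds = -A / (s * s)
    else:
        ristar = R * np.cos(theta)
        duds = (alpha * beta / (alpha - beta)) * Us0 * (
            -(ristar ** alpha) / s ** (alpha + 1.0)
            + ristar ** beta / s ** (beta + 1.0))
    # unit outward normal
    gx = x / (a_ax * a_ax * sq)
    gy = y / (b_ax * b_ax * sq)
    gz = z / (b_ax * b_ax * sq)
    gnorm = np.sqrt(gx * gx + gy * gy + gz * gz)
    # force = -dU/ds * grad s, grad s = -n_hat
    out[0] = duds * gx / gnorm
    out[1] = duds * gy / gnorm
    out[2] = duds * gz / gnorm


# ---------------------------------------------------------------------------
# volume correction

@njit(cache=True)
def lens_volume(d, Ri, Rj):
    """Volume of the intersection of two spheres at centre distance d."""
    if d >= Ri + Rj:
        return 0.0
    vi = 4.0 * np.pi * Ri ** 3 / 3.0
    vj = 4.0 * np.pi * Rj ** 3 / 3.0
    if d <= abs(Ri - Rj):
        return min(vi, vj)
    return (np.pi * (Ri + Rj - d) ** 2
            * (d * d + 2.0 * d * (Ri + Rj) - 3.0 * (Ri - Rj) ** 2)
            / (12.0 * d))


@njit(cache=True)
def corrected_radii(pos, R, adj, out):
    """Per-cell corrected radius R' absorbing pairwise overlap volume with
    current contact neighbours: 4/3 pi R'^3 = 4/3 pi R^3 + V_o."""
    n = R.shape[0]
    for i in range(n):
        vo = 0.0
        for j in range(n):
            if j != i and adj[i, j]:
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                d = np.sqrt(dx * dx + dy * dy + dz * dz)
                vo += lens_volume(d, R[i], R[j])
        out[i] = (R[i] ** 3 + 0.75 * vo / np.pi) ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# weighted-Voronoi contact inference

@njit(cache=True)
def _clip_area(C, m, half_width):
    """Area of the convex polygon {(s,t): C[q,0]*s + C[q,1]*t <= C[q,2]}
    intersected with the square [-half_width, half_width]^2.

    Incremental Sutherland-Hodgman clipping of the bounding square by each
    half-plane; returns 0 when the region empties.
    """
    px = np.empty(96)
    py = np.empty(96)
    qx = np.empty(96)
    qy = np.empty(96)
    px[0] = -half_width; py[0] = -half_width
    px[1] = half_width;  py[1] = -half_width
    px[2] = half_width;  py[2] = half_width
    px[3] = -half_width; py[3] = half_width
    nv = 4
    for q in range(m):
        c1 = C[q, 0]
        c2 = C[q, 1]
        h = C[q, 2]
        if c1 * c1 + c2 * c2 < 1e-24:
            if h < 0.0:
                return 0.0
            continue
        nn = 0
        for v in range(nv):
            ax = px[v]; ay = py[v]
            w = v + 1
            if w == nv:
                w = 0
            bx = px[w]; by = py[w]
            fa = c1 * ax + c2 * ay - h
            fb = c1 * bx + c2 * by - h
            if fa <= 0.0:
                qx[nn] = ax; qy[nn] = ay
                nn += 1
            if (fa > 0.0) != (fb > 0.0):
                t = fa / (fa - fb)
                qx[nn] = ax + t * (bx - ax)
                qy[nn] = ay + t * (by - ay)
                nn += 1
        if nn < 3:
            return 0.0
        for v in range(nn):
            px[v] = qx[v]
            py[v] = qy[v]
        nv = nn
    area = 0.0
    for v in range(nv):
        w = v + 1
        if w == nv:
            w = 0
        area += px[v] * py[w] - px[w] * py[v]
    return abs(area) * 0.5


@njit(cache=True)
def face_exists(i, j, pos, R, Rp, eps_area):
    """True when the weighted bisector plane between cells i and j carries a
    face of positive area of both clipped Voronoi polyhedra.

    Each cell's polyhedron is a regular dodecahedron (fixed canonical
    orientation) of inradius Rp (the volume-corrected radius), clipped by
    the weighted plane toward every other cell; the plane toward cell k sits
    at distance r_ik * R_i/(R_i + R_k) from cell i (proportional split by
    base radii, reducing to the midplane for equal radii).  The shared-face
    test is solved exactly in 2D on the mutual plane.
    """
    n = R.shape[0]
    dx = pos[j, 0] - pos[i, 0]
    dy = pos[j, 1] - pos[i, 1]
    dz = pos[j, 2] - pos[i, 2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    ux = dx / r
    uy = dy / r
    uz = dz / r
    di = r * R[i] / (R[i] + R[j])
    dj = r - di
    # plane beyond either dodecahedron's circumradius -> no face possible
    if di > Rp[i] * DODEC_CIRC_OVER_IN or dj > Rp[j] * DODEC_CIRC_OVER_IN:
        return False
    # point on the mutual plane where the centre line crosses it
    p0x = pos[i, 0] + di * ux
    p0y = pos[i, 1] + di * uy
    p0z = pos[i, 2] + di * uz
    # orthonormal in-plane basis
    if abs(ux) < 0.9:
        e1x = 1.0 - ux * ux
        e1y = -ux * uy
        e1z = -ux * uz
    else:
        e1x = -uy * ux
        e1y = 1.0 - uy * uy
        e1z = -uy * uz
    inv = 1.0 / np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x *= inv; e1y *= inv; e1z *= inv
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x

    maxc = 24 + 2 * (n - 2)
    C = np.empty((maxc, 3))
    m = 0
    # dodecahedral faces of both cells: nf . (x - pos_cell) <= Rp_cell
    for cell in range(2):
        ci = i if cell == 0 else j
        ox = p0x - pos[ci, 0]
        oy = p0y - pos[ci, 1]
        oz = p0z - pos[ci, 2]
        for k in range(12):
            nfx = DODEC_NORMALS[k, 0]
            nfy = DODEC_NORMALS[k, 1]
            nfz = DODEC_NORMALS[k, 2]
            C[m, 0] = nfx * e1x + nfy * e1y + nfz * e1z
            C[m, 1] = nfx * e2x + nfy * e2y + nfz * e2z
            C[m, 2] = Rp[ci] - (nfx * ox + nfy * oy + nfz * oz)
            m += 1
    # weighted planes toward every other cell, from both i's and j's side
    for k in range(n):
        if k == i or k == j:
            continue
        for cell in range(2):
            ci = i if cell == 0 else j
            wx = pos[k, 0] - pos[ci, 0]
            wy = pos[k, 1] - pos[ci, 1]
            wz = pos[k, 2] - pos[ci, 2]
            rk = np.sqrt(wx * wx + wy * wy + wz * wz)
            wx /= rk; wy /= rk; wz /= rk
            dk = rk * R[ci] / (R[ci] + R[k])
            ox = p0x - pos[ci, 0]
            oy = p0y - pos[ci, 1]
            oz = p0z - pos[ci, 2]
            C[m, 0] = wx * e1x + wy * e1y + wz * e1z
            C[m, 1] = wx * e2x + wy * e2y + wz * e2z
            C[m, 2] = dk - (wx * ox + wy * oy + wz * oz)
            m += 1
    # quick accept: if the axis point sits strictly inside every half-plane
    # with a safe margin, the face contains a disc of that radius
    minslack = 1e30
    for q in range(m):
        c1 = C[q, 0]
        c2 = C[q, 1]
        nn = np.sqrt(c1 * c1 + c2 * c2)
        if nn < 1e-12:
            if C[q, 2] < 0.0:
                return False
            continue
        slack = C[q, 2] / nn
        if slack < minslack:
            minslack = slack
    if minslack > 1e-4:
        return True
    # ambiguous: exact polygon clip
    hw = 2.0 * max(Rp[i], Rp[j]) * DODEC_CIRC_OVER_IN
    return _clip_area(C, m, hw) > eps_area


@njit(cache=True)
def contact_matrix(pos, R, Rp, adj):
    """Fill the symmetric contact adjacency matrix: cells are in contact
    when r_ij < R_i + R_j (base radii) AND their Voronoi polyhedra share
    a face; the volume-corrected radii R' only scale the dodecahedra."""
    n = R.shape[0]
    for i in range(n):
        for j in range(n):
            adj[i, j] = False
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < R[i] + R[j]:
                if face_exists(i, j, pos, R, Rp, EPS_FACE_AREA):
                    adj[i, j] = True
                    adj[j, i] = True


@njit(cache=True)
def distance_adjacency(pos, R, adj):
    """Plain distance-cutoff adjacency (bootstrap before the first Voronoi
    pass, and oracle baseline: dropping the Voronoi constraint can only add
    edges)."""
    n = R.shape[0]
    for i in range(n):
        for j in range(n):
            adj[i, j] = False
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < R[i] + R[j]:
                adj[i, j] = True
                adj[j, i] = True


# ---------------------------------------------------------------------------
# topology classification (4 nodes, fast path)

@njit(cache=True)
def classify4(adj):
    """Classify a 4-node contact graph by edge count and degree sequence
    (equivalent to isomorphism against the five reference graphs)."""
    deg = np.zeros(4, np.int64)
    m = 0
    for i in range(4):
        for j in range(i + 1, 4):
            if adj[i, j]:
                deg[i] += 1
                deg[j] += 1
                m += 1
    dmin = deg.min()
    dmax = deg.max()
    if m == 3 and dmax == 2 and dmin == 1:
        return LAB_LINE
    if m == 3 and dmax == 3:
        return LAB_T_SHAPE
    if m == 4 and dmax == 2 and dmin == 2:
        return LAB_SQUARE
    if m == 5:
        return LAB_DIAMOND
    if m == 6:
        return LAB_TETRAHEDRON
    return LAB_OTHER


# ---------------------------------------------------------------------------
# forces and integrator

@njit(cache=True)
def total_forces(pos, R, adj, theta, alpha, beta, afrac,
                 kind, a_ax, b_ax, A, Us0, F):
    """Sum of contact pair forces and shell force on every cell."""
    n = R.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                du = pair_dudr(r, R[i], R[j], theta, alpha, beta, afrac)
                fx = -du * dx / r
                fy = -du * dy / r
                fz = -du * dz / r
                F[i, 0] += fx
                F[i, 1] += fy
                F[i, 2] += fz
                F[j, 0] -= fx
                F[j, 1] -= fy
                F[j, 2] -= fz
    if kind != SHELL_NONE:
        fs = np.empty(3)
        for i in range(n):
            shell_force(pos[i, 0], pos[i, 1], pos[i, 2], R[i], theta,
                        kind, a_ax, b_ax, A, Us0, alpha, beta, fs)
            F[i, 0] += fs[0]
            F[i, 1] += fs[1]
            F[i, 2] += fs[2]


@njit(cache=True)
def total_energy(pos, R, adj, theta, alpha, beta, afrac,
                 kind, a_ax, b_ax, A, Us0):
    """Total potential energy (contact pairs + shell), units U0."""
    n = R.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                e += pair_potential(r, R[i], R[j], theta, alpha, beta, afrac)
        if kind != SHELL_NONE:
            e += shell_potential(pos[i, 0], pos[i, 1], pos[i, 2], R[i],
                                 theta, kind, a_ax, b_ax, A, Us0, alpha, beta)
    return e


@njit(cache=True)
def em_run(pos, R, frozen, n_steps, dt, sigma, theta, alpha, beta, afrac,
           kind, a_ax, b_ax, A, Us0, contact_stride, target,
           sample_every, seed):
    """Euler-Maruyama integration of the overdamped Langevin dynamics.

    Each step: r_i += -grad U * dt + sqrt(2 sigma dt) * eta_i with eta_i iid
    standard Gaussians, followed by the volume correction (corrected radii
    from pairwise lens overlaps with current contacts) and, every
    `contact_stride` steps, a rebuild of the weighted-Voronoi contact graph.

    Cells flagged in `frozen` receive neither force nor noise.  `target`
    is a topology code (or -1): when >= 0 and the system has 4 cells, the
    run stops at the first rebuilt contact graph classifying to it.

    Returns (status, stop_step, Rp, adj, n_samples, t_buf, pos_buf, rp_buf,
    lab_buf); positions are advanced in place.  status: 0 completed,
    1 target reached, 2 shell penetration (a cell centre reached the shell).
    """
    np.random.seed(seed)
    n = R.shape[0]
    adj = np.zeros((n, n), np.bool_)
    Rp = np.empty(n)
    # bootstrap: distance pass -> corrected radii -> Voronoi pass
    distance_adjacency(pos, R, adj)
    corrected_radii(pos, R, adj, Rp)
    contact_matrix(pos, R, Rp, adj)
    corrected_radii(pos, R, adj, Rp)

    nbuf = n_steps // sample_every + 3
    t_buf = np.empty(nbuf)
    pos_buf = np.empty((nbuf, n, 3))
    rp_buf = np.empty((nbuf, n))
    lab_buf = np.empty(nbuf, np.int64)
    ns = 0

    lab = classify4(adj) if n == 4 else -1
    status = STATUS_COMPLETED
    stop_step = n_steps
    if kind != SHELL_NONE:
        for i in range(n):
            if not frozen[i] and ellipsoid_level(
                    pos[i, 0], pos[i, 1], pos[i, 2], a_ax, b_ax) >= 1.0:
                t_buf[0] = 0.0
                pos_buf[0] = pos
                rp_buf[0] = Rp
                lab_buf[0] = lab
                return (STATUS_PENETRATION, 0, Rp, adj, 1, t_buf, pos_buf,
                        rp_buf, lab_buf)
    if target >= 0 and n == 4 and lab == target:
        t_buf[0] = 0.0
        pos_buf[0] = pos
        rp_buf[0] = Rp
        lab_buf[0] = lab
        return STATUS_TARGET, 0, Rp, adj, 1, t_buf, pos_buf, rp_buf, lab_buf

    F = np.empty((n, 3))
    step = 0
    while step < n_steps:
        if step % sample_every == 0:
            t_buf[ns] = step * dt
            pos_buf[ns] = pos
            rp_buf[ns] = Rp
            lab_buf[ns] = lab
            ns += 1
        # adaptive substepping: cap the deterministic move per update at
        # MAX_STEP_DISP so stiff shell-core transients (e.g. a daughter
        # placed deep in the wall's divergent boundary layer) integrate
        # stably; forces are refreshed after every partial advance, so the
        # substep size recovers as the transient relaxes
        t_used = 0.0
        it = 0
        while t_used < dt and it < MAX_SUBSTEPS:
            it += 1
            total_forces(pos, R, adj, theta, alpha, beta, afrac,
                         kind, a_ax, b_ax, A, Us0, F)
            fmax = 0.0
            for i in range(n):
                if not frozen[i]:
                    fn = np.sqrt(F[i, 0] ** 2 + F[i, 1] ** 2 + F[i, 2] ** 2)
                    if fn > fmax:
                        fmax = fn
            h = dt - t_used
            if fmax * h > MAX_STEP_DISP:
                h = MAX_STEP_DISP / fmax
            sub_amp = np.sqrt(2.0 * sigma * h)
            for i in range(n):
                if frozen[i]:
                    continue
                for d in range(3):
                    eta = np.random.standard_normal()
                    pos[i, d] += F[i, d] * h + sub_amp * eta
            t_used += h
        step += 1
        if kind != SHELL_NONE:
            bad = False
            for i in range(n):
                if not frozen[i] and ellipsoid_level(
                        pos[i, 0], pos[i, 1], pos[i, 2], a_ax, b_ax) >= 1.0:
                    bad = True
            if bad:
                status = STATUS_PENETRATION
                stop_step = step
                break
        corrected_radii(pos, R, adj, Rp)
        if step % contact_stride == 0 or step == n_steps:
            contact_matrix(pos, R, Rp, adj)
            corrected_radii(pos, R, adj, Rp)
            if n == 4:
                lab = classify4(adj)
                if target >= 0 and lab == target:
                    status = STATUS_TARGET
                    stop_step = step
                    break
    if status == STATUS_COMPLETED:
        # make the final contact graph current even with a stride
        contact_matrix(pos, R, Rp, adj)
        corrected_radii(pos, R, adj, Rp)
        if n == 4:
            lab = classify4(adj)
    # final frame
    t_buf[ns] = stop_step * dt if status != STATUS_COMPLETED else n_steps * dt
    pos_buf[ns] = pos
    rp_buf[ns] = Rp
    lab_buf[ns] = lab
    ns += 1
    return status, stop_step, Rp, adj, ns, t_buf, pos_buf, rp_buf, lab_buf
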