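"""Numba-compiled numerical kernels.

Conventions used throughout the kernels:

* step-parameter arrays are ``(..., 6)`` float64 with columns
  ``(tilt, roll, twist, shift, slide, rise)`` in degrees / nm — the same
  units as the user-facing dataclasses; angles are converted to radians
  only where rotation matrices are built;
* base-pair frames are right-handed orthonormal 3x3 matrices whose
  columns are (short axis, long axis, normal), origins in nm;
* the step transform uses the symmetric mid-step convention:
  ``R = Rz(tw/2) @ Rbend(tilt, roll) @ Rz(tw/2)`` and the displacement
  ``(shift, slide, rise)`` is applied in the mid-step frame
  ``F_i @ sqrt(R)``.
"""

import numpy as np
from numba import njit

DEG = np.pi / 180.0


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rodrigues(vx, vy, vz):
    """Rotation matrix from a rotation vector (radians)."""
    R = np.empty((3, 3))
    theta = np.sqrt(vx * vx + vy * vy + vz * vz)
    if theta < 1e-12:
        R[:] = np.eye(3)
        # first-order term keeps tiny steps consistent
        R[0, 1] -= vz
        R[1, 0] += vz
        R[0, 2] += vy
        R[2, 0] -= vy
        R[1, 2] -= vx
        R[2, 1] += vx
        return R
    ux, uy, uz = vx / theta, vy / theta, vz / theta
    c = np.cos(theta)
    s = np.sin(theta)
    C = 1.0 - c
    R[0, 0] = c + ux * ux * C
    R[0, 1] = ux * uy * C - uz * s
    R[0, 2] = ux * uz * C + uy * s
    R[1, 0] = uy * ux * C + uz * s
    R[1, 1] = c + uy * uy * C
    R[1, 2] = uy * uz * C - ux * s
    R[2, 0] = uz * ux * C - uy * s
    R[2, 1] = uz * uy * C + ux * s
    R[2, 2] = c + uz * uz * C
    return R


@njit(cache=True)
def _mat_to_rotvec(R):
    """Rotation vector (radians) of a rotation matrix; |angle| < pi assumed
    away from the antipode (guarded)."""
    tr = R[0, 0] + R[1, 1] + R[2, 2]
    c = 0.5 * (tr - 1.0)
    if c > 1.0:
        c = 1.0
    if c < -1.0:
        c = -1.0
    theta = np.arccos(c)
    ax = R[2, 1] - R[1, 2]
    ay = R[0, 2] - R[2, 0]
    az = R[1, 0] - R[0, 1]
    n = np.sqrt(ax * ax + ay * ay + az * az)
    out = np.empty(3)
    if theta < 1e-8:
        out[0] = 0.5 * ax
        out[1] = 0.5 * ay
        out[2] = 0.5 * az
        return out
    if n < 1e-12:
        # theta ~ pi: extract axis from the symmetric part
        bxx = 0.5 * (R[0, 0] + 1.0)
        byy = 0.5 * (R[1, 1] + 1.0)
        bzz = 0.5 * (R[2, 2] + 1.0)
        ux = np.sqrt(max(bxx, 0.0))
        uy = np.sqrt(max(byy, 0.0))
        uz = np.sqrt(max(bzz, 0.0))
        if R[0, 1] + R[1, 0] < 0.0:
            uy = -uy
        if R[0, 2] + R[2, 0] < 0.0:
            uz = -uz
        out[0] = theta * ux
        out[1] = theta * uy
        out[2] = theta * uz
        return out
    f = theta / n
    out[0] = f * ax
    out[1] = f * ay
    out[2] = f * az
    return out


@njit(cache=True)
def _rz(a):
    R = np.eye(3)
    c = np.cos(a)
    s = np.sin(a)
    R[0, 0] = c
    R[0, 1] = -s
    R[1, 0] = s
    R[1, 1] = c
    return R


@njit(cache=True)
def step_rotation(tilt_deg, roll_deg, twist_deg):
    """Full rotation of one base-pair step (frame i -> frame i+1)."""
    tw = twist_deg * DEG
    half = _rz(0.5 * tw)
    bend = _rodrigues(tilt_deg * DEG, roll_deg * DEG, 0.0)
    return half @ bend @ half


@njit(cache=True)
def step_transform(step):
    """Rotation R and local displacement d of one step.

    origin_{i+1} = origin_i + F_i @ d ;  F_{i+1} = F_i @ R
    with d expressed through the mid-step frame sqrt(R).
    """
    R = step_rotation(step[0], step[1], step[2])
    v = _mat_to_rotvec(R)
    Rh = _rodrigues(0.5 * v[0], 0.5 * v[1], 0.5 * v[2])
    d = np.empty(3)
    d[0] = Rh[0, 0] * step[3] + Rh[0, 1] * step[4] + Rh[0, 2] * step[5]
    d[1] = Rh[1, 0] * step[3] + Rh[1, 1] * step[4] + Rh[1, 2] * step[5]
    d[2] = Rh[2, 0] * step[3] + Rh[2, 1] * step[4] + Rh[2, 2] * step[5]
    return R, d


@njit(cache=True)
def _orthonormalize(F):
    """Gram-Schmidt re-orthonormalization preserving handedness."""
    out = np.empty((3, 3))
    x = F[:, 0]
    nx = np.sqrt(x[0] ** 2 + x[1] ** 2 + x[2] ** 2)
    x = x / nx
    y = F[:, 1]
    d = x[0] * y[0] + x[1] * y[1] + x[2] * y[2]
    y = y - d * x
    ny = np.sqrt(y[0] ** 2 + y[1] ** 2 + y[2] ** 2)
    y = y / ny
    z = np.empty(3)
    z[0] = x[1] * y[2] - x[2] * y[1]
    z[1] = x[2] * y[0] - x[0] * y[2]
    z[2] = x[0] * y[1] - x[1] * y[0]
    out[:, 0] = x
    out[:, 1] = y
    out[:, 2] = z
    return out


@njit(cache=True)
def build_chain(start_origin, start_frame, steps):
    """Compound steps from a start frame.

    Returns (origins (N+1, 3), frames (N+1, 3, 3)).
    """
    n = steps.shape[0]
    origins = np.empty((n + 1, 3))
    frames = np.empty((n + 1, 3, 3))
    origins[0] = start_origin
    frames[0] = _orthonormalize(start_frame)
    for i in range(n):
        R, d = step_transform(steps[i])
        F = frames[i]
        origins[i + 1, 0] = origins[i, 0] + F[0, 0] * d[0] + F[0, 1] * d[1] + F[0, 2] * d[2]
        origins[i + 1, 1] = origins[i, 1] + F[1, 0] * d[0] + F[1, 1] * d[1] + F[1, 2] * d[2]
        origins[i + 1, 2] = origins[i, 2] + F[2, 0] * d[0] + F[2, 1] * d[1] + F[2, 2] * d[2]
        frames[i + 1] = _orthonormalize(F @ R)
    return origins, frames


@njit(cache=True)
def extract_steps(origins, frames):
    """Invert build_chain: step parameters between consecutive frames."""
    n = origins.shape[0] - 1
    steps = np.empty((n, 6))
    for i in range(n):
        R = frames[i].T @ frames[i + 1]
        # R = Rod_h(Gamma) @ Rz(twist); bend angle from the normal images
        czz = R[2, 2]
        if czz > 1.0:
            czz = 1.0
        if czz < -1.0:
            czz = -1.0
        gamma = np.arccos(czz)
        if gamma < 1e-10:
            twist = np.arctan2(R[1, 0], R[0, 0])
            tilt = 0.0
            roll = 0.0
        else:
            hx = -R[1, 2]
            hy = R[0, 2]
            hn = np.sqrt(hx * hx + hy * hy)
            hx /= hn
            hy /= hn
            Rb = _rodrigues(-gamma * hx, -gamma * hy, 0.0)
            Rt = Rb @ R
            twist = np.arctan2(Rt[1, 0], Rt[0, 0])
            # bend axis in mid-step phase: a = Rz(-tw/2) @ h
            ca = np.cos(-0.5 * twist)
            sa = np.sin(-0.5 * twist)
            axx = ca * hx - sa * hy
            axy = sa * hx + ca * hy
            tilt = gamma * axx
            roll = gamma * axy
        v = _mat_to_rotvec(R)
        Rh = _rodrigues(0.5 * v[0], 0.5 * v[1], 0.5 * v[2])
        dx = origins[i + 1, 0] - origins[i, 0]
        dy = origins[i + 1, 1] - origins[i, 1]
        dz = origins[i + 1, 2] - origins[i, 2]
        F = frames[i]
        lx = F[0, 0] * dx + F[1, 0] * dy + F[2, 0] * dz
        ly = F[0, 1] * dx + F[1, 1] * dy + F[2, 1] * dz
        lz = F[0, 2] * dx + F[1, 2] * dy + F[2, 2] * dz
        steps[i, 0] = tilt / DEG
        steps[i, 1] = roll / DEG
        steps[i, 2] = twist / DEG
        steps[i, 3] = Rh[0, 0] * lx + Rh[1, 0] * ly + Rh[2, 0] * lz
        steps[i, 4] = Rh[0, 1] * lx + Rh[1, 1] * ly + Rh[2, 1] * lz
        steps[i, 5] = Rh[0, 2] * lx + Rh[1, 2] * ly + Rh[2, 2] * lz
    return steps


# ---------------------------------------------------------------------------
# writhe / linking number
# ---------------------------------------------------------------------------

@njit(cache=True)
def _unit(v):
    n = np.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
    if n < 1e-14:
        return v * 0.0
    return v / n


@njit(cache=True)
def _tri_solid_angle(a, b, c):
    """Signed solid angle of the spherical triangle spanned by unit
    vectors a, b, c (van Oosterom & Strackee): robust for all
    configurations, range (-2pi, 2pi)."""
    num = (a[0] * (b[1] * c[2] - b[2] * c[1])
           + a[1] * (b[2] * c[0] - b[0] * c[2])
           + a[2] * (b[0] * c[1] - b[1] * c[0]))
    den = (1.0
           + a[0] * b[0] + a[1] * b[1] + a[2] * b[2]
           + b[0] * c[0] + b[1] * c[1] + b[2] * c[2]
           + c[0] * a[0] + c[1] * a[1] + c[2] * a[2])
    return 2.0 * np.arctan2(num, den)


@njit(cache=True)
def _pair_solid_angle(p1, p2, p3, p4):
    """Signed solid angle of the quadrilateral spanned on the unit sphere
    by the inter-segment direction vectors; the contribution of the
    segment pair (p1,p2), (p3,p4) to 2*pi*Wr.  Split into two spherical
    triangles evaluated with the atan2 formula, which has no branch
    ambiguities."""
    a = _unit(p3 - p1)   # r13
    b = _unit(p4 - p1)   # r14
    c = _unit(p4 - p2)   # r24
    d = _unit(p3 - p2)   # r23
    if (a[0] == 0.0 and a[1] == 0.0 and a[2] == 0.0) or \
       (b[0] == 0.0 and b[1] == 0.0 and b[2] == 0.0) or \
       (c[0] == 0.0 and c[1] == 0.0 and c[2] == 0.0) or \
       (d[0] == 0.0 and d[1] == 0.0 and d[2] == 0.0):
        return 0.0
    return -(_tri_solid_angle(a, b, c) + _tri_solid_angle(a, c, d))


@njit(cache=True)
def writhe_exact(verts):
    """Writhe of a closed polygon via exact per-segment-pair solid angles."""
    n = verts.shape[0]
    total = 0.0
    for i in range(n):
        p1 = verts[i]
        p2 = verts[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            q1 = verts[j]
            q2 = verts[(j + 1) % n]
            total += _pair_solid_angle(p1, p2, q1, q2)
    return total / (2.0 * np.pi)


@njit(cache=True)
def writhe_quadrature(verts):
    """Writhe by midpoint quadrature of the Gauss double integral."""
    n = verts.shape[0]
    mids = np.empty((n, 3))
    tans = np.empty((n, 3))
    for i in range(n):
        j = (i + 1) % n
        mids[i] = 0.5 * (verts[i] + verts[j])
        tans[i] = verts[j] - verts[i]
    total = 0.0
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            rx = mids[i, 0] - mids[j, 0]
            ry = mids[i, 1] - mids[j, 1]
            rz = mids[i, 2] - mids[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            r3 = r2 * np.sqrt(r2)
            if r3 < 1e-14:
                continue
            cx = tans[i, 1] * tans[j, 2] - tans[i, 2] * tans[j, 1]
            cy = tans[i, 2] * tans[j, 0] - tans[i, 0] * tans[j, 2]
            cz = tans[i, 0] * tans[j, 1] - tans[i, 1] * tans[j, 0]
            total += (cx * rx + cy * ry + cz * rz) / r3
    return total / (2.0 * np.pi)


@njit(cache=True)
def linking_number(verts1, verts2):
    """Gauss linking number of two closed polygons (exact pair formula)."""
    n1 = verts1.shape[0]
    n2 = verts2.shape[0]
    total = 0.0
    for i in range(n1):
        p1 = verts1[i]
        p2 = verts1[(i + 1) % n1]
        for j in range(n2):
            total += _pair_solid_angle(p1, p2, verts2[j], verts2[(j + 1) % n2])
    return total / (4.0 * np.pi)


@njit(cache=True)
def ribbon_twist(origins, normals, closed):
    """Total twist (turns) of a discrete ribbon.

    ``origins`` (N,3) axis vertices, ``normals`` (N,3) material vectors
    (need not be exactly perpendicular to the local tangent; they are
    projected).  Edge i runs from vertex i to i+1; the twist is the sum of
    signed angles between the parallel-transported normal and the next
    normal, about each edge tangent.
    """
    n = origins.shape[0]
    nseg = n if closed else n - 1
    # edge tangents
    t = np.empty((nseg, 3))
    for i in range(nseg):
        j = (i + 1) % n
        v = origins[j] - origins[i]
        t[i] = v / np.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    # per-edge normals: project vertex normal i onto plane of edge i
    u = np.empty((nseg, 3))
    for i in range(nseg):
        v = normals[i]
        d = v[0] * t[i, 0] + v[1] * t[i, 1] + v[2] * t[i, 2]
        w = v - d * t[i]
        u[i] = w / np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
    total = 0.0
    nstep = nseg if closed else nseg - 1
    for i in range(nstep):
        j = (i + 1) % nseg
        # parallel transport u[i] from t[i] to t[j]
        cx = t[i, 1] * t[j, 2] - t[i, 2] * t[j, 1]
        cy = t[i, 2] * t[j, 0] - t[i, 0] * t[j, 2]
        cz = t[i, 0] * t[j, 1] - t[i, 1] * t[j, 0]
        cn = np.sqrt(cx * cx + cy * cy + cz * cz)
        dt = t[i, 0] * t[j, 0] + t[i, 1] * t[j, 1] + t[i, 2] * t[j, 2]
        if dt > 1.0:
            dt = 1.0
        if dt < -1.0:
            dt = -1.0
        if cn < 1e-14:
            up = u[i].copy()
        else:
            ang = np.arctan2(cn, dt)
            R = _rodrigues(ang * cx / cn, ang * cy / cn, ang * cz / cn)
            up = R @ u[i]
        # signed angle from up to u[j] about t[j]
        dotp = up[0] * u[j, 0] + up[1] * u[j, 1] + up[2] * u[j, 2]
        crx = up[1] * u[j, 2] - up[2] * u[j, 1]
        cry = up[2] * u[j, 0] - up[0] * u[j, 2]
        crz = up[0] * u[j, 1] - up[1] * u[j, 0]
        sinp = crx * t[j, 0] + cry * t[j, 1] + crz * t[j, 2]
        total += np.arctan2(sinp, dotp)
    return total / (2.0 * np.pi)


# ---------------------------------------------------------------------------
# fiber geometry
# ---------------------------------------------------------------------------

@njit(cache=True)
def place_cores_and_linkers(start_t, start_R, entry_to_exit_R, entry_to_exit_t,
                            linker_steps, n_cores):
    """Propagate core placements through per-linker step lists.

    Core i is placed by the world transform (R_i, t_i) of its entry frame;
    core 0 at the identity.  ``entry_to_exit_R/t`` map the core's entry
    frame to its exit frame in core-local coordinates (exit_F = R_entry @
    entry_to_exit_R, exit origin = R_entry @ entry_to_exit_t + t_entry).
    ``linker_steps`` is (n_linkers, L+1, 6); the chain of L+1 steps from a
    core's exit frame ends on the next core's entry frame, producing L free
    linker base pairs in between.

    Returns core_R (n,3,3), core_t (n,3), linker_pts (n_linkers, L, 3).
    """
    n_link = linker_steps.shape[0]
    L = linker_steps.shape[1] - 1
    core_R = np.empty((n_cores, 3, 3))
    core_t = np.empty((n_cores, 3))
    linker_pts = np.empty((n_link, L, 3))
    core_R[0] = start_R
    core_t[0] = start_t
    for i in range(n_link):
        R = core_R[i % n_cores]
        t = core_t[i % n_cores]
        eo = np.empty(3)
        eo[0] = R[0, 0] * entry_to_exit_t[0] + R[0, 1] * entry_to_exit_t[1] + R[0, 2] * entry_to_exit_t[2] + t[0]
        eo[1] = R[1, 0] * entry_to_exit_t[0] + R[1, 1] * entry_to_exit_t[1] + R[1, 2] * entry_to_exit_t[2] + t[1]
        eo[2] = R[2, 0] * entry_to_exit_t[0] + R[2, 1] * entry_to_exit_t[1] + R[2, 2] * entry_to_exit_t[2] + t[2]
        eF = R @ entry_to_exit_R
        origins, frames = build_chain(eo, eF, linker_steps[i])
        for k in range(L):
            linker_pts[i, k] = origins[k + 1]
        if i + 1 < n_cores:
            core_R[i + 1] = frames[L + 1]
            core_t[i + 1] = origins[L + 1]
    return core_R, core_t, linker_pts


@njit(cache=True)
def core_world_centers_axes(core_R, core_t, center_local, axis_local):
    n = core_R.shape[0]
    centers = np.empty((n, 3))
    axes = np.empty((n, 3))
    for i in range(n):
        R = core_R[i]
        for a in range(3):
            centers[i, a] = (R[a, 0] * center_local[0] + R[a, 1] * center_local[1]
                             + R[a, 2] * center_local[2] + core_t[i, a])
            axes[i, a] = R[a, 0] * axis_local[0] + R[a, 1] * axis_local[1] + R[a, 2] * axis_local[2]
    return centers, axes


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

@njit(cache=True)
def elastic_energy_steps(steps, eq, K):
    """Sum of harmonic step energies: 0.5 * d^T K d per step (degrees/nm)."""
    total = 0.0
    ns = steps.shape[0]
    for i in range(ns):
        d = steps[i] - eq
        for a in range(6):
            for b in range(6):
                total += 0.5 * d[a] * K[a, b] * d[b]
    return total


@njit(cache=True)
def stacking_pair(ci, ai, cj, aj, depth, dist0, width, wlat):
    """Face-to-face stacking well between two cores (kT, <= 0).

    The separation is decomposed along the mean superhelical axis:
    the well sits at axial distance ``dist0`` with radial width ``width``,
    a lateral Gaussian of width ``wlat`` requires the faces to overlap,
    and |cos| of the axis angle modulates the depth.
    """
    dx = ci[0] - cj[0]
    dy = ci[1] - cj[1]
    dz = ci[2] - cj[2]
    d2 = dx * dx + dy * dy + dz * dz
    cutoff = dist0 + 3.0 * width + 3.0 * wlat
    if d2 >= cutoff * cutoff:
        return 0.0
    dot = ai[0] * aj[0] + ai[1] * aj[1] + ai[2] * aj[2]
    g = abs(dot)
    # mean stacking axis
    s = 1.0 if dot >= 0.0 else -1.0
    mx = ai[0] + s * aj[0]
    my = ai[1] + s * aj[1]
    mz = ai[2] + s * aj[2]
    mn = np.sqrt(mx * mx + my * my + mz * mz)
    if mn < 1e-12:
        return 0.0
    mx /= mn
    my /= mn
    mz /= mn
    d_ax = abs(dx * mx + dy * my + dz * mz)
    d_lat2 = d2 - d_ax * d_ax
    if d_lat2 < 0.0:
        d_lat2 = 0.0
    u = (d_ax - dist0) / width
    v2 = d_lat2 / (wlat * wlat)
    if 0.5 * (u * u + v2) > 60.0:
        return 0.0
    return -depth * np.exp(-0.5 * (u * u + v2)) * g


@njit(cache=True)
def stacking_total(centers, axes, depth, dist0, width, wlat):
    """Sum of pairwise attractive stacking wells (kT, negative)."""
    n = centers.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += stacking_pair(centers[i], axes[i], centers[j], axes[j],
                                   depth, dist0, width, wlat)
    return total


@njit(cache=True)
def _point_in_cylinder(p, c, a, radius, half_h):
    dx = p[0] - c[0]
    dy = p[1] - c[1]
    dz = p[2] - c[2]
    ax = dx * a[0] + dy * a[1] + dz * a[2]
    if abs(ax) > half_h:
        return False
    r2 = dx * dx + dy * dy + dz * dz - ax * ax
    return r2 < radius * radius


@njit(cache=True)
def _core_spheres(c, a, radius, half_h):
    """Sphere-set model of an oblate core cylinder: one central sphere of
    radius half_h plus a ring of 8 at ring radius (radius - half_h).
    Accurate for disc-like bodies (radius >= half_h) with slightly
    rounded rims."""
    out = np.empty((9, 3))
    out[0] = c
    if abs(a[0]) < 0.9:
        ex = np.array([1.0, 0.0, 0.0])
    else:
        ex = np.array([0.0, 1.0, 0.0])
    u = np.empty(3)
    u[0] = a[1] * ex[2] - a[2] * ex[1]
    u[1] = a[2] * ex[0] - a[0] * ex[2]
    u[2] = a[0] * ex[1] - a[1] * ex[0]
    un = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    u /= un
    v = np.empty(3)
    v[0] = a[1] * u[2] - a[2] * u[1]
    v[1] = a[2] * u[0] - a[0] * u[2]
    v[2] = a[0] * u[1] - a[1] * u[0]
    rr = radius - half_h
    for k in range(8):
        ang = 2.0 * np.pi * k / 8.0
        cs = np.cos(ang)
        sn = np.sin(ang)
        for a3 in range(3):
            out[k + 1, a3] = c[a3] + rr * (cs * u[a3] + sn * v[a3])
    return out


@njit(cache=True)
def _all_core_spheres(centers, axes, radius, half_h):
    n = centers.shape[0]
    out = np.empty((n, 9, 3))
    for i in range(n):
        out[i] = _core_spheres(centers[i], axes[i], radius, half_h)
    return out


@njit(cache=True)
def _cylinders_overlap(c1, a1, c2, a2, radius, half_h):
    """Overlap test for two congruent oblate core cylinders via the
    sphere-set model (any sphere pair closer than 2*half_h)."""
    dx = c1[0] - c2[0]
    dy = c1[1] - c2[1]
    dz = c1[2] - c2[2]
    d2 = dx * dx + dy * dy + dz * dz
    rmax = 2.0 * radius
    if d2 > rmax * rmax:
        return False
    s1 = _core_spheres(c1, a1, radius, half_h)
    s2 = _core_spheres(c2, a2, radius, half_h)
    dmin2 = (2.0 * half_h) ** 2
    for i in range(9):
        for j in range(9):
            dx = s1[i, 0] - s2[j, 0]
            dy = s1[i, 1] - s2[j, 1]
            dz = s1[i, 2] - s2[j, 2]
            if dx * dx + dy * dy + dz * dz < dmin2:
                return True
    return False


@njit(cache=True)
def _seg_seg_dist2(p1, p2, q1, q2):
    """Squared minimum distance between segments [p1,p2] and [q1,q2]."""
    ux = p2[0] - p1[0]
    uy = p2[1] - p1[1]
    uz = p2[2] - p1[2]
    vx = q2[0] - q1[0]
    vy = q2[1] - q1[1]
    vz = q2[2] - q1[2]
    wx = p1[0] - q1[0]
    wy = p1[1] - q1[1]
    wz = p1[2] - q1[2]
    a = ux * ux + uy * uy + uz * uz
    b = ux * vx + uy * vy + uz * vz
    c = vx * vx + vy * vy + vz * vz
    d = ux * wx + uy * wy + uz * wz
    e = vx * wx + vy * wy + vz * wz
    D = a * c - b * b
    if D < 1e-12:
        sN, sD = 0.0, 1.0
        tN, tD = e, c
    else:
        sN = b * e - c * d
        sD = D
        tN = a * e - b * d
        tD = D
        if sN < 0.0:
            sN = 0.0
            tN, tD = e, c
        elif sN > sD:
            sN = sD
            tN, tD = e + b, c
    if tN < 0.0:
        tN = 0.0
        if -d < 0.0:
            sN = 0.0
        elif -d > a:
            sN = sD
        else:
            sN = -d
            sD = a
    elif tN > tD:
        tN = tD
        if (-d + b) < 0.0:
            sN = 0.0
        elif (-d + b) > a:
            sN = sD
        else:
            sN = -d + b
            sD = a
    s = 0.0 if abs(sN) < 1e-12 else sN / sD
    t = 0.0 if abs(tN) < 1e-12 else tN / tD
    dx = wx + s * ux - t * vx
    dy = wy + s * uy - t * vy
    dz = wz + s * uz - t * vz
    return dx * dx + dy * dy + dz * dz


#: octamer (histone-core) cylinder used for linker-DNA clash checks; it
#: sits inside the wrapped DNA so legitimately crossing linkers clear it.
OCTAMER_RADIUS = 3.2
OCTAMER_HALF_H = 2.3


@njit(cache=True)
def _wrap_world(core_R, core_t, wrap_local):
    n = core_R.shape[0]
    nw = wrap_local.shape[0]
    wrap_w = np.empty((n, nw, 3))
    for j in range(n):
        R = core_R[j]
        t = core_t[j]
        for k in range(nw):
            for a3 in range(3):
                wrap_w[j, k, a3] = (R[a3, 0] * wrap_local[k, 0]
                                    + R[a3, 1] * wrap_local[k, 1]
                                    + R[a3, 2] * wrap_local[k, 2] + t[a3])
    return wrap_w


@njit(cache=True)
def _linker_bounds(linker_pts):
    n_link = linker_pts.shape[0]
    lo = np.empty((n_link, 3))
    hi = np.empty((n_link, 3))
    for il in range(n_link):
        for a in range(3):
            lo[il, a] = linker_pts[il, :, a].min()
            hi[il, a] = linker_pts[il, :, a].max()
    return lo, hi


@njit(cache=True)
def _boxes_touch(lo, hi, i, j, pad):
    for a in range(3):
        if lo[i, a] - pad > hi[j, a] or lo[j, a] - pad > hi[i, a]:
            return False
    return True


@njit(cache=True)
def excluded_volume_overlap(core_R, core_t, centers, axes, wrap_local,
                            linker_pts, core_radius, core_half_h,
                            dna_radius, check_linker_linker):
    """Total squared overlap depth (nm^2) of the hard-core constraints.

    Zero iff the conformation is strictly clash-free:

    * non-adjacent core cylinders (oblate sphere-set model) must not
      interpenetrate;
    * linker base pairs must stay out of the histone-octamer cylinder of
      every core but the two the linker joins, and at least 2*dna_radius
      from that core's wrapped-DNA proxy points;
    * linker segments separated by >= 8 steps of DNA contour must stay
      2*dna_radius apart (stride-2 subsampling; optional, it dominates
      the cost).
    """
    total = 0.0
    n = centers.shape[0]
    dmin = 2.0 * core_half_h
    spheres = _all_core_spheres(centers, axes, core_radius, core_half_h)
    for i in range(n):
        for j in range(i + 2, n):
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            if dx * dx + dy * dy + dz * dz > (2.0 * core_radius) ** 2:
                continue
            for ii in range(9):
                for jj in range(9):
                    ax = spheres[i, ii, 0] - spheres[j, jj, 0]
                    ay = spheres[i, ii, 1] - spheres[j, jj, 1]
                    az = spheres[i, ii, 2] - spheres[j, jj, 2]
                    d = np.sqrt(ax * ax + ay * ay + az * az)
                    if d < dmin:
                        total += (dmin - d) ** 2
    n_link = linker_pts.shape[0]
    L = linker_pts.shape[1]
    nw = wrap_local.shape[0]
    rr = OCTAMER_RADIUS + dna_radius
    hh = OCTAMER_HALF_H + dna_radius
    ddna = 2.0 * dna_radius
    wrap_w = _wrap_world(core_R, core_t, wrap_local)
    # wrapped DNA of sequence-adjacent cores may not interpenetrate;
    # non-adjacent pairs are already excluded by the enclosing cylinders
    for i in range(n - 1):
        j = i + 1
        dx = centers[i, 0] - centers[j, 0]
        dy = centers[i, 1] - centers[j, 1]
        dz = centers[i, 2] - centers[j, 2]
        if dx * dx + dy * dy + dz * dz <= 169.0:
            for ki in range(nw):
                for kj in range(nw):
                    ax = wrap_w[i, ki, 0] - wrap_w[j, kj, 0]
                    ay = wrap_w[i, ki, 1] - wrap_w[j, kj, 1]
                    az = wrap_w[i, ki, 2] - wrap_w[j, kj, 2]
                    d = np.sqrt(ax * ax + ay * ay + az * az)
                    if d < ddna:
                        total += (ddna - d) ** 2
    for il in range(n_link):
        for k in range(L):
            p = linker_pts[il, k]
            for j in range(n):
                if j == il or j == il + 1:
                    continue
                dx = p[0] - centers[j, 0]
                dy = p[1] - centers[j, 1]
                dz = p[2] - centers[j, 2]
                d2c = dx * dx + dy * dy + dz * dz
                if d2c > 100.0:
                    continue  # > 10 nm from center: cannot touch this core
                # octamer body: penetration depth
                axl = dx * axes[j, 0] + dy * axes[j, 1] + dz * axes[j, 2]
                rad = np.sqrt(max(d2c - axl * axl, 0.0))
                if abs(axl) < hh and rad < rr:
                    pen = min(hh - abs(axl), rr - rad)
                    total += pen * pen
                # wrapped DNA of the foreign core
                for w in range(nw):
                    ax = p[0] - wrap_w[j, w, 0]
                    ay = p[1] - wrap_w[j, w, 1]
                    az = p[2] - wrap_w[j, w, 2]
                    d = np.sqrt(ax * ax + ay * ay + az * az)
                    if d < ddna:
                        total += (ddna - d) ** 2
    if check_linker_linker:
        lo, hi = _linker_bounds(linker_pts)
        for il in range(n_link):
            for jl in range(il, n_link):
                if jl != il and not _boxes_touch(lo, hi, il, jl, ddna):
                    continue
                for k in range(0, L - 1, 3):
                    k2 = min(k + 3, L - 1)
                    for m in range(0, L - 1, 3):
                        if jl == il and m < k + 9:
                            continue
                        m2 = min(m + 3, L - 1)
                        d2 = _seg_seg_dist2(linker_pts[il, k], linker_pts[il, k2],
                                            linker_pts[jl, m], linker_pts[jl, m2])
                        if d2 < ddna * ddna:
                            total += (ddna - np.sqrt(d2)) ** 2
    return total


@njit(cache=True)
def excluded_volume_violated(core_R, core_t, centers, axes, wrap_local,
                             linker_pts, core_radius, core_half_h,
                             dna_radius, check_linker_linker, tol=0.1):
    """Hard-core check: True iff any pairwise overlap exceeds the contact
    tolerance ``tol`` (nm)."""
    n = centers.shape[0]
    dmin = 2.0 * core_half_h - tol
    spheres = _all_core_spheres(centers, axes, core_radius, core_half_h)
    for i in range(n):
        for j in range(i + 2, n):
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            if dx * dx + dy * dy + dz * dz > (2.0 * core_radius) ** 2:
                continue
            for ii in range(9):
                for jj in range(9):
                    ax = spheres[i, ii, 0] - spheres[j, jj, 0]
                    ay = spheres[i, ii, 1] - spheres[j, jj, 1]
                    az = spheres[i, ii, 2] - spheres[j, jj, 2]
                    if np.sqrt(ax * ax + ay * ay + az * az) < dmin:
                        return True
    n_link = linker_pts.shape[0]
    L = linker_pts.shape[1]
    nw = wrap_local.shape[0]
    rr = OCTAMER_RADIUS + dna_radius - tol
    hh = OCTAMER_HALF_H + dna_radius - tol
    ddna = 2.0 * dna_radius - tol
    wrap_w = _wrap_world(core_R, core_t, wrap_local)
    for i in range(n - 1):
        j = i + 1
        dx = centers[i, 0] - centers[j, 0]
        dy = centers[i, 1] - centers[j, 1]
        dz = centers[i, 2] - centers[j, 2]
        if dx * dx + dy * dy + dz * dz <= 169.0:
            for ki in range(nw):
                for kj in range(nw):
                    ax = wrap_w[i, ki, 0] - wrap_w[j, kj, 0]
                    ay = wrap_w[i, ki, 1] - wrap_w[j, kj, 1]
                    az = wrap_w[i, ki, 2] - wrap_w[j, kj, 2]
                    if ax * ax + ay * ay + az * az < ddna * ddna:
                        return True
    for il in range(n_link):
        for k in range(L):
            p = linker_pts[il, k]
            for j in range(n):
                if j == il or j == il + 1:
                    continue
                dx = p[0] - centers[j, 0]
                dy = p[1] - centers[j, 1]
                dz = p[2] - centers[j, 2]
                d2c = dx * dx + dy * dy + dz * dz
                if d2c > 100.0:
                    continue
                axl = dx * axes[j, 0] + dy * axes[j, 1] + dz * axes[j, 2]
                rad = np.sqrt(max(d2c - axl * axl, 0.0))
                if abs(axl) < hh and rad < rr:
                    return True
                for w in range(nw):
                    ax = p[0] - wrap_w[j, w, 0]
                    ay = p[1] - wrap_w[j, w, 1]
                    az = p[2] - wrap_w[j, w, 2]
                    if ax * ax + ay * ay + az * az < ddna * ddna:
                        return True
    if check_linker_linker:
        lo, hi = _linker_bounds(linker_pts)
        for il in range(n_link):
            for jl in range(il, n_link):
                if jl != il and not _boxes_touch(lo, hi, il, jl, ddna):
                    continue
                for k in range(0, L - 1, 3):
                    k2 = min(k + 3, L - 1)
                    for m in range(0, L - 1, 3):
                        if jl == il and m < k + 9:
                            continue
                        m2 = min(m + 3, L - 1)
                        if _seg_seg_dist2(linker_pts[il, k], linker_pts[il, k2],
                                          linker_pts[jl, m], linker_pts[jl, m2]) < ddna * ddna:
                            return True
    return False


@njit(cache=True)
def fiber_energy(core_R, core_t, centers, axes, wrap_local, linker_steps,
                 linker_pts, eq, K, depth, dist0, width, wlat, core_radius,
                 core_half_h, dna_radius, ev_on, check_linker_linker):
    """(elastic, stacking, violated) for a placed fiber."""
    nl = linker_steps.shape[0]
    el = 0.0
    for i in range(nl):
        el += elastic_energy_steps(linker_steps[i], eq, K)
    st = stacking_total(centers, axes, depth, dist0, width, wlat)
    viol = False
    if ev_on:
        viol = excluded_volume_violated(core_R, core_t, centers, axes,
                                        wrap_local, linker_pts, core_radius,
                                        core_half_h, dna_radius,
                                        check_linker_linker)
    return el, st, viol


# ---------------------------------------------------------------------------
# uniform (regular) fibers
# ---------------------------------------------------------------------------

@njit(cache=True)
def uniform_fiber_geometry(step6, L, n_cores, entry_to_exit_R, entry_to_exit_t):
    """Regular fiber: every linker step identical.  Returns core placements
    and free linker points, as place_cores_and_linkers does."""
    linker_steps = np.empty((n_cores - 1, L + 1, 6))
    for i in range(n_cores - 1):
        for k in range(L + 1):
            linker_steps[i, k] = step6
    return place_cores_and_linkers(np.zeros(3), np.eye(3), entry_to_exit_R,
                                   entry_to_exit_t, linker_steps, n_cores)


@njit(cache=True)
def uniform_fiber_energy(step6, L, n_cores, entry_to_exit_R, entry_to_exit_t,
                         center_local, axis_local, wrap_local, eq, K, depth,
                         dist0, width, wlat, core_radius, core_half_h,
                         dna_radius, ev_on, check_linker_linker):
    core_R, core_t, linker_pts = uniform_fiber_geometry(
        step6, L, n_cores, entry_to_exit_R, entry_to_exit_t)
    centers, axes = core_world_centers_axes(core_R, core_t, center_local, axis_local)
    nl = n_cores - 1
    d = step6 - eq
    e1 = 0.0
    for a in range(6):
        for b in range(6):
            e1 += 0.5 * d[a] * K[a, b] * d[b]
    el = e1 * nl * (L + 1)
    st = stacking_total(centers, axes, depth, dist0, width, wlat)
    if ev_on:
        viol = excluded_volume_violated(core_R, core_t, centers, axes,
                                        wrap_local, linker_pts, core_radius,
                                        core_half_h, dna_radius,
                                        check_linker_linker)
        if viol:
            return 1e12, True
    return el + st, False


@njit(cache=True)
def uniform_fiber_soft_energy(step6, L, n_cores, entry_to_exit_R,
                              entry_to_exit_t, center_local, axis_local,
                              wrap_local, eq, K, depth, dist0, width, wlat,
                              core_radius, core_half_h, dna_radius,
                              check_linker_linker, w_overlap):
    """Elastic + stacking + quadratic excluded-volume penalty, for
    boundary-following optimization of regular fibers."""
    core_R, core_t, linker_pts = uniform_fiber_geometry(
        step6, L, n_cores, entry_to_exit_R, entry_to_exit_t)
    centers, axes = core_world_centers_axes(core_R, core_t, center_local, axis_local)
    nl = n_cores - 1
    d = step6 - eq
    e1 = 0.0
    for a in range(6):
        for b in range(6):
            e1 += 0.5 * d[a] * K[a, b] * d[b]
    el = e1 * nl * (L + 1)
    st = stacking_total(centers, axes, depth, dist0, width, wlat)
    ov = excluded_volume_overlap(core_R, core_t, centers, axes, wrap_local,
                                 linker_pts, core_radius, core_half_h,
                                 dna_radius, check_linker_linker)
    return el + st + w_overlap * ov


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@njit(cache=True)
def mc_run(linker_steps0, L, n_cores, entry_to_exit_R, entry_to_exit_t,
           center_local, axis_local, wrap_local, eq, K, depth, dist0, width,
           wlat, core_radius, core_half_h, dna_radius, ev_on,
           check_linker_linker, temperature, n_steps, move_angle, move_disp,
           seed, record_every):
    """Metropolis MC over per-linker step parameters.

    One move = one random parameter of one random step of one random linker
    perturbed uniformly.  Returns recorded snapshots (linker step params,
    core placements, centers/axes), the energy trace and acceptance rate.
    """
    np.random.seed(seed)
    n_link = linker_steps0.shape[0]
    steps = linker_steps0.copy()
    core_R, core_t, linker_pts = place_cores_and_linkers(
        np.zeros(3), np.eye(3), entry_to_exit_R, entry_to_exit_t, steps, n_cores)
    centers, axes = core_world_centers_axes(core_R, core_t, center_local, axis_local)
    el, st, viol = fiber_energy(core_R, core_t, centers, axes, wrap_local,
                                steps, linker_pts, eq, K, depth, dist0, width,
                                wlat, core_radius, core_half_h, dna_radius,
                                ev_on, check_linker_linker)
    energy = el + st
    n_rec = n_steps // record_every
    rec_steps = np.empty((n_rec, n_link, L + 1, 6))
    rec_core_R = np.empty((n_rec, n_cores, 3, 3))
    rec_core_t = np.empty((n_rec, n_cores, 3))
    rec_energy = np.empty(n_rec)
    accepted = 0
    irec = 0
    for it in range(n_steps):
        jl = np.random.randint(0, n_link)
        jk = np.random.randint(0, L + 1)
        jm = np.random.randint(0, 6)
        if jm < 3:
            delta = (2.0 * np.random.random() - 1.0) * move_angle
        else:
            delta = (2.0 * np.random.random() - 1.0) * move_disp
        old_val = steps[jl, jk, jm]
        steps[jl, jk, jm] = old_val + delta
        # rebuild from linker jl onward
        new_core_R = core_R.copy()
        new_core_t = core_t.copy()
        new_linker_pts = linker_pts.copy()
        R0 = core_R[jl]
        t0 = core_t[jl]
        eo = np.empty(3)
        for a in range(3):
            eo[a] = (R0[a, 0] * entry_to_exit_t[0] + R0[a, 1] * entry_to_exit_t[1]
                     + R0[a, 2] * entry_to_exit_t[2] + t0[a])
        eF = R0 @ entry_to_exit_R
        origins, frames = build_chain(eo, eF, steps[jl])
        for k in range(L):
            new_linker_pts[jl, k] = origins[k + 1]
        if jl + 1 < n_cores:
            # rigid update of everything downstream of core jl+1
            old_R = core_R[jl + 1]
            old_t = core_t[jl + 1]
            new_R = frames[L + 1]
            new_t = origins[L + 1]
            D = new_R @ old_R.T
            new_core_R[jl + 1] = new_R
            new_core_t[jl + 1] = new_t
            for c in range(jl + 2, n_cores):
                new_core_R[c] = D @ core_R[c]
                for a in range(3):
                    new_core_t[c, a] = (D[a, 0] * (core_t[c, 0] - old_t[0])
                                        + D[a, 1] * (core_t[c, 1] - old_t[1])
                                        + D[a, 2] * (core_t[c, 2] - old_t[2])
                                        + new_t[a])
            for c in range(jl + 1, n_link):
                for k in range(L):
                    px = linker_pts[c, k, 0] - old_t[0]
                    py = linker_pts[c, k, 1] - old_t[1]
                    pz = linker_pts[c, k, 2] - old_t[2]
                    new_linker_pts[c, k, 0] = D[0, 0] * px + D[0, 1] * py + D[0, 2] * pz + new_t[0]
                    new_linker_pts[c, k, 1] = D[1, 0] * px + D[1, 1] * py + D[1, 2] * pz + new_t[1]
                    new_linker_pts[c, k, 2] = D[2, 0] * px + D[2, 1] * py + D[2, 2] * pz + new_t[2]
        new_centers, new_axes = core_world_centers_axes(
            new_core_R, new_core_t, center_local, axis_local)
        nel, nst, nviol = fiber_energy(new_core_R, new_core_t, new_centers,
                                       new_axes, wrap_local, steps,
                                       new_linker_pts, eq, K, depth, dist0,
                                       width, wlat, core_radius, core_half_h,
                                       dna_radius, ev_on, check_linker_linker)
        accept = False
        if not nviol:
            dE = (nel + nst) - energy
            if dE <= 0.0:
                accept = True
            else:
                x = dE / temperature
                if x < 700.0 and np.random.random() < np.exp(-x):
                    accept = True
        if accept:
            core_R = new_core_R
            core_t = new_core_t
            linker_pts = new_linker_pts
            centers = new_centers
            axes = new_axes
            energy = nel + nst
            accepted += 1
        else:
            steps[jl, jk, jm] = old_val
        if (it + 1) % record_every == 0 and irec < n_rec:
            rec_steps[irec] = steps
            rec_core_R[irec] = core_R
            rec_core_t[irec] = core_t
            rec_energy[irec] = energy
            irec += 1
    return rec_steps, rec_core_R, rec_core_t, rec_energy, accepted / n_steps
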