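"""Numba kernels: voxel ray attenuation, diamond-difference sweeps, analog MC.

All kernels are single-threaded and deterministic for fixed inputs (and, for
the MC kernel, a fixed seed).  Geometry arguments are in mm; cross sections
in 1/cm; track lengths are converted at the tally site.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MM_PER_CM = 10.0
_TINY = 1e-12


# ---------------------------------------------------------------------------
# Ray attenuation (Siddon/Amanatides-Woo style parametric marching)

@njit(cache=True)
def _ray_tau(p0, p1, origin, spacing, sigma_t, tau):
    """Accumulate per-group optical depth along segment p0 -> p1 into tau.

    sigma_t has shape (G, nx, ny, nz) in 1/cm; p0, p1 in mm.
    """
    G = sigma_t.shape[0]
    nx, ny, nz = sigma_t.shape[1], sigma_t.shape[2], sigma_t.shape[3]
    for g in range(G):
        tau[g] = 0.0
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    dz = p1[2] - p0[2]
    seg_len = np.sqrt(dx * dx + dy * dy + dz * dz)
    if seg_len <= 0.0:
        return
    # parametric entry/exit of the grid, t in [0, 1]
    tmin = 0.0
    tmax = 1.0
    d = (dx, dy, dz)
    n = (nx, ny, nz)
    for a in range(3):
        lo = origin[a]
        hi = origin[a] + n[a] * spacing[a]
        if abs(d[a]) < _TINY:
            if p0[a] < lo or p0[a] >= hi:
                return
        else:
            t1 = (lo - p0[a]) / d[a]
            t2 = (hi - p0[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin:
        return
    t = tmin
    # current voxel from a point just inside
    eps = 1e-9
    tprobe = tmin + eps * (tmax - tmin)
    i = int((p0[0] + tprobe * dx - origin[0]) / spacing[0])
    j = int((p0[1] + tprobe * dy - origin[1]) / spacing[1])
    k = int((p0[2] + tprobe * dz - origin[2]) / spacing[2])
    if i < 0:
        i = 0
    if j < 0:
        j = 0
    if k < 0:
        k = 0
    if i > nx - 1:
        i = nx - 1
    if j > ny - 1:
        j = ny - 1
    if k > nz - 1:
        k = nz - 1
    while t < tmax - _TINY:
        # parametric distance to the next plane along each axis
        tnext = tmax
        if abs(dx) > _TINY:
            step = 1 if dx > 0 else 0
            tx = (origin[0] + (i + step) * spacing[0] - p0[0]) / dx
            if tx < tnext:
                tnext = tx
        if abs(dy) > _TINY:
            step = 1 if dy > 0 else 0
            ty = (origin[1] + (j + step) * spacing[1] - p0[1]) / dy
            if ty < tnext:
                tnext = ty
        if abs(dz) > _TINY:
            step = 1 if dz > 0 else 0
            tz = (origin[2] + (k + step) * spacing[2] - p0[2]) / dz
            if tz < tnext:
                tnext = tz
        if tnext < t + _TINY:
            tnext = t + _TINY
        if tnext > tmax:
            tnext = tmax
        chord_cm = (tnext - t) * seg_len / MM_PER_CM
        for g in range(G):
            tau[g] += sigma_t[g, i, j, k] * chord_cm
        t = tnext
        if t >= tmax - _TINY:
            break
        # advance into the next voxel
        tprobe = t + eps * (tmax - tmin)
        i = int((p0[0] + tprobe * dx - origin[0]) / spacing[0])
        j = int((p0[1] + tprobe * dy - origin[1]) / spacing[1])
        k = int((p0[2] + tprobe * dz - origin[2]) / spacing[2])
        if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
            break


@njit(cache=True)
def uncollided_one_source(
    src, origin, spacing, sigma_t, spec_share, ii, jj, kk, out
):
    """Uncollided fluence contribution of one source at listed voxels.

    out has shape (G, nx, ny, nz); adds share*spec_g/(4 pi d_cm^2) e^{-tau_g}
    at each voxel center in (ii, jj, kk).
    """
    G = sigma_t.shape[0]
    tau = np.zeros(G)
    p1 = np.zeros(3)
    four_pi = 4.0 * np.pi
    for m in range(ii.shape[0]):
        i, j, k = ii[m], jj[m], kk[m]
        p1[0] = origin[0] + (i + 0.5) * spacing[0]
        p1[1] = origin[1] + (j + 0.5) * spacing[1]
        p1[2] = origin[2] + (k + 0.5) * spacing[2]
        dxm = p1[0] - src[0]
        dym = p1[1] - src[1]
        dzm = p1[2] - src[2]
        d_cm = np.sqrt(dxm * dxm + dym * dym + dzm * dzm) / MM_PER_CM
        _ray_tau(src, p1, origin, spacing, sigma_t, tau)
        geom = 1.0 / (four_pi * d_cm * d_cm)
        for g in range(G):
            out[g, i, j, k] += spec_share[g] * geom * np.exp(-tau[g])


# ---------------------------------------------------------------------------
# Diamond-difference transport sweep

@njit(cache=True)
def sweep_group_kernel(
    sigma_t, q0, q1, use_p1, dirs, wts, spacing_cm, fixup, phi, J, store_psi, psi
):
    """One full sweep over all directions for a single energy group.

    sigma_t, q0: (nx, ny, nz); q1: (nx, ny, nz, 3); dirs/wts: quadrature.
    Writes the scalar fluence into phi and the current into J; returns
    (leakage, n_fixups).  Vacuum boundaries: zero incoming on all faces.
    """
    nx, ny, nz = sigma_t.shape
    dx, dy, dz = spacing_cm[0], spacing_cm[1], spacing_cm[2]
    phi[:] = 0.0
    J[:] = 0.0
    leak = 0.0
    nfix = 0
    fx = np.zeros((ny, nz))
    fy = np.zeros(nz)
    n_dir = dirs.shape[0]
    area_x = dy * dz
    area_y = dx * dz
    area_z = dx * dy
    for nd in range(n_dir):
        mu = dirs[nd, 0]
        eta = dirs[nd, 1]
        xi = dirs[nd, 2]
        w = wts[nd]
        ax = 2.0 * abs(mu) / dx
        ay = 2.0 * abs(eta) / dy
        az = 2.0 * abs(xi) / dz
        si = 1 if mu > 0 else -1
        sj = 1 if eta > 0 else -1
        sk = 1 if xi > 0 else -1
        i0 = 0 if si > 0 else nx - 1
        j0 = 0 if sj > 0 else ny - 1
        k0 = 0 if sk > 0 else nz - 1
        fx[:, :] = 0.0
        for ic in range(nx):
            i = i0 + si * ic
            for jc in range(ny):
                j = j0 + sj * jc
                if jc == 0:
                    for k in range(nz):
                        fy[k] = 0.0
                fz = 0.0
                for kc in range(nz):
                    k = k0 + sk * kc
                    pin_x = fx[j, k]
                    pin_y = fy[k]
                    pin_z = fz
                    qn = q0[i, j, k]
                    if use_p1:
                        qn += 3.0 * (
                            mu * q1[i, j, k, 0]
                            + eta * q1[i, j, k, 1]
                            + xi * q1[i, j, k, 2]
                        )
                    st = sigma_t[i, j, k]
                    denom = st + ax + ay + az
                    pc = (qn + ax * pin_x + ay * pin_y + az * pin_z) / denom
                    out_x = 2.0 * pc - pin_x
                    out_y = 2.0 * pc - pin_y
                    out_z = 2.0 * pc - pin_z
                    if fixup and (out_x < 0.0 or out_y < 0.0 or out_z < 0.0):
                        # set-to-zero fixup with local rebalance
                        free_x = True
                        free_y = True
                        free_z = True
                        # up to 3 faces can be fixed; one extra pass ensures
                        # the final center solve is balanced for the final set
                        for _it in range(4):
                            # cell balance with a = ax/2 = |mu|/dx per face:
                            # free face: out = 2 pc - pin; fixed face: out = 0
                            num = qn
                            den = st
                            if free_x:
                                num += ax * pin_x
                                den += ax
                            else:
                                num += 0.5 * ax * pin_x
                            if free_y:
                                num += ay * pin_y
                                den += ay
                            else:
                                num += 0.5 * ay * pin_y
                            if free_z:
                                num += az * pin_z
                                den += az
                            else:
                                num += 0.5 * az * pin_z
                            pc = num / den
                            bad = False
                            if free_x:
                                out_x = 2.0 * pc - pin_x
                                if out_x < 0.0:
                                    free_x = False
                                    bad = True
                            if free_y:
                                out_y = 2.0 * pc - pin_y
                                if out_y < 0.0:
                                    free_y = False
                                    bad = True
                            if free_z:
                                out_z = 2.0 * pc - pin_z
                                if out_z < 0.0:
                                    free_z = False
                                    bad = True
                            if not bad:
                                break
                        if not free_x:
                            out_x = 0.0
                        if not free_y:
                            out_y = 0.0
                        if not free_z:
                            out_z = 0.0
                        if pc < 0.0:
                            pc = 0.0
                        nfix += 1
                    fx[j, k] = out_x
                    fy[k] = out_y
                    fz = out_z
                    if store_psi:
                        psi[nd, i, j, k] = pc
                    phi[i, j, k] += w * pc
                    J[i, j, k, 0] += w * mu * pc
                    J[i, j, k, 1] += w * eta * pc
                    J[i, j, k, 2] += w * xi * pc
                    # leakage through exterior outgoing faces
                    if kc == nz - 1:
                        leak += w * abs(xi) * out_z * area_z
                    if jc == ny - 1:
                        leak += w * abs(eta) * out_y * area_y
        # x leakage from the stored outgoing faces of the final slab
        for j2 in range(ny):
            for k2 in range(nz):
                leak += w * abs(mu) * fx[j2, k2] * area_x
    return leak, nfix


# ---------------------------------------------------------------------------
# Analog multigroup Monte Carlo (track-length tallies)

@njit(cache=True)
def _rotate(ux, uy, uz, mu_s, phi_s):
    """Rotate direction u by scattering cosine mu_s and azimuth phi_s."""
    sin_t = np.sqrt(max(0.0, 1.0 - mu_s * mu_s))
    cp = np.cos(phi_s)
    sp = np.sin(phi_s)
    if abs(uz) < 0.99999:
        den = np.sqrt(1.0 - uz * uz)
        vx = ux * uz * cp / den - uy * sp / den
        vy = uy * uz * cp / den + ux * sp / den
        vz = -den * cp
        wx = ux * mu_s + sin_t * vx
        wy = uy * mu_s + sin_t * vy
        wz = uz * mu_s + sin_t * vz
    else:
        # near-polar incident direction: use a simple stable frame
        wx = sin_t * cp
        wy = sin_t * sp
        wz = mu_s * (1.0 if uz > 0 else -1.0)
    norm = np.sqrt(wx * wx + wy * wy + wz * wz)
    return wx / norm, wy / norm, wz / norm


@njit(cache=True)
def _sample_linear_mu(a):
    """Sample mu in [-1, 1] from density (1 + a*mu)/2, |a| <= 1."""
    xi = np.random.random()
    if abs(a) < 1e-9:
        return 2.0 * xi - 1.0
    disc = 1.0 - a * (2.0 - a - 4.0 * xi)
    if disc < 0.0:
        disc = 0.0
    return (-1.0 + np.sqrt(disc)) / a


@njit(cache=True)
def mc_batch_kernel(
    seed,
    n_hist,
    origin,
    spacing,
    mat_index,
    scale,
    sig_t,
    p_survive,
    grp_cdf,
    a_coef,
    src_pos,
    src_axis_u,
    src_axis_v,
    src_axis_w,
    src_kind,
    src_cos_half,
    src_phi_deg,
    src_theta_deg,
    src_weight,
    spec_cdf,
    dose_factor,
    tally_unc,
    tally_col,
    tally_dose,
):
    """Run one batch of analog histories; accumulate track-length tallies.

    mat_index: (nx,ny,nz) int16; scale: density/reference_density per voxel.
    sig_t: (nmat, G); p_survive: (nmat, G) scattering probability at collision;
    grp_cdf: (nmat, G, G) conditional CDF over outgoing group given scatter;
    a_coef: (nmat, G, G) linear-anisotropy coefficient (3*mu_bar, clipped).
    src_kind: 0 point, 1 cone, 2 fan.  spec_cdf: (S, G).  dose_factor: (G,).
    Returns (n_clip_events, n_terminated_below_cutoff).
    """
    np.random.seed(seed)
    nx, ny, nz = mat_index.shape
    G = sig_t.shape[1]
    S = src_pos.shape[0]
    n_clip = 0
    n_cutoff = 0
    for _h in range(n_hist):
        # --- source sampling
        s = int(np.random.random() * S)
        if s >= S:
            s = S - 1
        # collimated sources tally with their solid-angle fraction so that
        # fluence is per particle of the underlying isotropic focal spot
        wt = src_weight[s]
        xi = np.random.random()
        g = 0
        for gg in range(G):
            if xi <= spec_cdf[s, gg]:
                g = gg
                break
        kind = src_kind[s]
        if kind == 0:
            cmu = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            st_ = np.sqrt(1.0 - cmu * cmu)
            ux = st_ * np.cos(phi)
            uy = st_ * np.sin(phi)
            uz = cmu
        elif kind == 1:
            # uniform over solid angle within the cone about the axis
            cmu = src_cos_half[s] + np.random.random() * (1.0 - src_cos_half[s])
            phi = 2.0 * np.pi * np.random.random()
            st_ = np.sqrt(max(0.0, 1.0 - cmu * cmu))
            lu = st_ * np.cos(phi)
            lv = st_ * np.sin(phi)
            lw = cmu
            ux = lu * src_axis_u[s, 0] + lv * src_axis_v[s, 0] + lw * src_axis_w[s, 0]
            uy = lu * src_axis_u[s, 1] + lv * src_axis_v[s, 1] + lw * src_axis_w[s, 1]
            uz = lu * src_axis_u[s, 2] + lv * src_axis_v[s, 2] + lw * src_axis_w[s, 2]
        else:
            # fan: rejection inside the bounding cone
            phi_h = src_phi_deg[s] * np.pi / 180.0
            th_h = src_theta_deg[s] * np.pi / 180.0
            bound = phi_h if phi_h > th_h else th_h
            cbound = np.cos(bound)
            while True:
                cmu = cbound + np.random.random() * (1.0 - cbound)
                phi = 2.0 * np.pi * np.random.random()
                st_ = np.sqrt(max(0.0, 1.0 - cmu * cmu))
                lu = st_ * np.cos(phi)
                lv = st_ * np.sin(phi)
                lw = cmu
                azim = np.arctan2(abs(lu), lw)
                polar = np.arcsin(min(1.0, abs(lv)))
                if azim <= phi_h + 1e-12 and polar <= th_h + 1e-12:
                    break
            ux = lu * src_axis_u[s, 0] + lv * src_axis_v[s, 0] + lw * src_axis_w[s, 0]
            uy = lu * src_axis_u[s, 1] + lv * src_axis_v[s, 1] + lw * src_axis_w[s, 1]
            uz = lu * src_axis_u[s, 2] + lv * src_axis_v[s, 2] + lw * src_axis_w[s, 2]
        px = src_pos[s, 0]
        py = src_pos[s, 1]
        pz = src_pos[s, 2]
        # --- fly to the grid if outside
        lox = origin[0]
        hix = origin[0] + nx * spacing[0]
        loy = origin[1]
        hiy = origin[1] + ny * spacing[1]
        loz = origin[2]
        hiz = origin[2] + nz * spacing[2]
        inside = lox <= px < hix and loy <= py < hiy and loz <= pz < hiz
        if not inside:
            tmin = 0.0
            tmax = 1.0e30
            ok = True
            for a in range(3):
                if a == 0:
                    p_, d_, lo_, hi_ = px, ux, lox, hix
                elif a == 1:
                    p_, d_, lo_, hi_ = py, uy, loy, hiy
                else:
                    p_, d_, lo_, hi_ = pz, uz, loz, hiz
                if abs(d_) < _TINY:
                    if p_ < lo_ or p_ >= hi_:
                        ok = False
                        break
                else:
                    t1 = (lo_ - p_) / d_
                    t2 = (hi_ - p_) / d_
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > tmin:
                        tmin = t1
                    if t2 < tmax:
                        tmax = t2
            if (not ok) or tmax <= tmin or tmax <= 0.0:
                continue  # never enters the grid
            adv = tmin + 1e-7 * spacing[0]
            px += ux * adv
            py += uy * adv
            pz += uz * adv
        # --- transport
        ncoll = 0
        alive = True
        while alive:
            # floor, not int(): truncation toward zero would map a position
            # just below the low boundary to index 0 and trap the history
            i = int(np.floor((px - lox) / spacing[0]))
            j = int(np.floor((py - loy) / spacing[1]))
            k = int(np.floor((pz - loz) / spacing[2]))
            if i < 0 or j < 0 or k < 0 or i >= nx or j >= ny or k >= nz:
                break  # escaped (vacuum boundary)
            m = mat_index[i, j, k]
            sg = sig_t[m, g] * scale[i, j, k]
            # distance to voxel exit (mm)
            d_exit = 1.0e30
            if abs(ux) > _TINY:
                step = 1 if ux > 0 else 0
                tx = (lox + (i + step) * spacing[0] - px) / ux
                if tx < d_exit:
                    d_exit = tx
            if abs(uy) > _TINY:
                step = 1 if uy > 0 else 0
                ty = (loy + (j + step) * spacing[1] - py) / uy
                if ty < d_exit:
                    d_exit = ty
            if abs(uz) > _TINY:
                step = 1 if uz > 0 else 0
                tz = (loz + (k + step) * spacing[2] - pz) / uz
                if tz < d_exit:
                    d_exit = tz
            if d_exit < 0.0:
                d_exit = 0.0
            if sg > _TINY:
                s_col = -np.log(np.random.random()) / sg * MM_PER_CM
            else:
                s_col = 1.0e30
            if s_col < d_exit:
                # collision inside this voxel
                track_cm = wt * s_col / MM_PER_CM
                if ncoll == 0:
                    tally_unc[g, i, j, k] += track_cm
                else:
                    tally_col[g, i, j, k] += track_cm
                tally_dose[i, j, k] += dose_factor[g] * track_cm
                px += ux * s_col
                py += uy * s_col
                pz += uz * s_col
                if np.random.random() >= p_survive[m, g]:
                    alive = False  # absorbed
                    break
                # outgoing group
                xi2 = np.random.random()
                g2 = G  # below-cutoff removal if no bin matched
                for gg in range(g, G):
                    if xi2 <= grp_cdf[m, g, gg]:
                        g2 = gg
                        break
                if g2 == G:
                    n_cutoff += 1
                    alive = False
                    break
                a_ = a_coef[m, g, g2]
                mu_s = _sample_linear_mu(a_)
                phi_s = 2.0 * np.pi * np.random.random()
                ux, uy, uz = _rotate(ux, uy, uz, mu_s, phi_s)
                g = g2
                ncoll += 1
            else:
                # cross into the next voxel
                track_cm = wt * d_exit / MM_PER_CM
                if ncoll == 0:
                    tally_unc[g, i, j, k] += track_cm
                else:
                    tally_col[g, i, j, k] += track_cm
                tally_dose[i, j, k] += dose_factor[g] * track_cm
                adv = d_exit + 1e-7 * spacing[0]
                px += ux * adv
                py += uy * adv
                pz += uz * adv
    return n_clip, n_cutoff
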