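"""Numba kernels: force evaluation and Langevin integration.

All arrays are float64/int64; masses are 1 in reduced units; kB = 1.
Energy components are accumulated into a fixed-layout vector:

    0 bonded, 1 intra, 2 inter, 3 linker, 4 binary_basin,
    5 binding, 6 electrostatic, 7 excluded

The per-contact epsilon passed in is already scaled (rho applied upstream),
so the kernel never sees the force-field object.
"""

import numpy as np
from numba import njit

N_COMPONENTS = 8

# bias kinds
BIAS_NONE = 0
BIAS_UMBRELLA = 1
BIAS_METAD = 2

_ENERGY_GUARD = 1.0e8


@njit(cache=True)
def forces_energy(
    pos, frozen,
    bonds, bond_r0, k_bond,
    angles, angle_t0, k_angle,
    dihs, dih_p0, k_dih,
    ci, cj, csigma, ceps, cclass,
    ev_i, ev_j, ev_sigma,
    el_i, el_j, el_qq, dh_a, dh_lambda,
    rescale,
    force_out,
):
    n = pos.shape[0]
    comps = np.zeros(N_COMPONENTS)
    for k in range(n):
        force_out[k, 0] = 0.0
        force_out[k, 1] = 0.0
        force_out[k, 2] = 0.0

    # bonds
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        comps[0] += k_bond * dr * dr
        fmag = -2.0 * k_bond * dr / r
        force_out[i, 0] += fmag * dx
        force_out[i, 1] += fmag * dy
        force_out[i, 2] += fmag * dz
        force_out[j, 0] -= fmag * dx
        force_out[j, 1] -= fmag * dy
        force_out[j, 2] -= fmag * dz

    # angles
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dtheta = theta - angle_t0[a]
        comps[0] += k_angle * dtheta * dtheta
        s = np.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            s = 1.0e-8
        dvdt = 2.0 * k_angle * dtheta
        coef = -dvdt / s
        # d(theta)/dri = (c*u_hat - v_hat) / (nu * s) with sign folded in coef
        fix = coef * (c * ux / nu - vx / nv) / nu
        fiy = coef * (c * uy / nu - vy / nv) / nu
        fiz = coef * (c * uz / nu - vz / nv) / nu
        fkx = coef * (c * vx / nv - ux / nu) / nv
        fky = coef * (c * vy / nv - uy / nu) / nv
        fkz = coef * (c * vz / nv - uz / nu) / nv
        force_out[i, 0] += fix
        force_out[i, 1] += fiy
        force_out[i, 2] += fiz
        force_out[k, 0] += fkx
        force_out[k, 1] += fky
        force_out[k, 2] += fkz
        force_out[j, 0] -= fix + fkx
        force_out[j, 1] -= fiy + fky
        force_out[j, 2] -= fiz + fkz

    # dihedrals: V = K[(1 - cos(dphi)) + 0.5(1 - cos 3 dphi)]
    for d in range(dihs.shape[0]):
        i = dihs[d, 0]
        j = dihs[d, 1]
        k = dihs[d, 2]
        l = dihs[d, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # phi = atan2((n1 x n2) . b2_hat, n1 . n2)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        y = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        x = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(y, x)
        dphi = phi - dih_p0[d]
        comps[0] += k_dih * (
            (1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi))
        )
        dvdphi = k_dih * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1.0e-12 or n2sq < 1.0e-12:
            continue
        fi_coef = dvdphi * nb2 / n1sq
        fl_coef = -dvdphi * nb2 / n2sq
        fix = fi_coef * n1x
        fiy = fi_coef * n1y
        fiz = fi_coef * n1z
        flx = fl_coef * n2x
        fly = fl_coef * n2y
        flz = fl_coef * n2z
        sfac = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        tfac = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        fjx = -fix - sfac * fix + tfac * flx
        fjy = -fiy - sfac * fiy + tfac * fly
        fjz = -fiz - sfac * fiz + tfac * flz
        fkx = -flx + sfac * fix - tfac * flx
        fky = -fly + sfac * fiy - tfac * fly
        fkz = -flz + sfac * fiz - tfac * flz
        force_out[i, 0] += fix
        force_out[i, 1] += fiy
        force_out[i, 2] += fiz
        force_out[j, 0] += fjx
        force_out[j, 1] += fjy
        force_out[j, 2] += fjz
        force_out[k, 0] += fkx
        force_out[k, 1] += fky
        force_out[k, 2] += fkz
        force_out[l, 0] += flx
        force_out[l, 1] += fly
        force_out[l, 2] += flz

    # native contacts, 12-10: V = eps (5 u^12 - 6 u^10), u = sigma / r
    for c_ in range(ci.shape[0]):
        i = ci[c_]
        j = cj[c_]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        u2 = (csigma[c_] * csigma[c_]) / r2
        u10 = u2 * u2 * u2 * u2 * u2
        u12 = u10 * u2
        comps[cclass[c_] + 1] += ceps[c_] * (5.0 * u12 - 6.0 * u10)
        # -dV/dr / r
        fmag = 60.0 * ceps[c_] * (u12 - u10) / r2
        force_out[i, 0] += fmag * dx
        force_out[i, 1] += fmag * dy
        force_out[i, 2] += fmag * dz
        force_out[j, 0] -= fmag * dx
        force_out[j, 1] -= fmag * dy
        force_out[j, 2] -= fmag * dz

    # excluded volume: V = (s/r)^12 for non-contact nonbonded pairs
    ev_s2 = ev_sigma * ev_sigma
    for e in range(ev_i.shape[0]):
        i = ev_i[e]
        j = ev_j[e]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > 9.0 * ev_s2:
            continue
        u2 = ev_s2 / r2
        u12 = u2 * u2 * u2 * u2 * u2 * u2
        comps[7] += u12
        fmag = 12.0 * u12 / r2
        force_out[i, 0] += fmag * dx
        force_out[i, 1] += fmag * dy
        force_out[i, 2] += fmag * dz
        force_out[j, 0] -= fmag * dx
        force_out[j, 1] -= fmag * dy
        force_out[j, 2] -= fmag * dz

    # Debye-Hueckel electrostatics
    for e in range(el_i.shape[0]):
        i = el_i[e]
        j = el_j[e]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        v = dh_a * el_qq[e] * np.exp(-r / dh_lambda) / r
        comps[6] += v
        fmag = v * (1.0 / dh_lambda + 1.0 / r) / r
        force_out[i, 0] += fmag * dx
        force_out[i, 1] += fmag * dy
        force_out[i, 2] += fmag * dz
        force_out[j, 0] -= fmag * dx
        force_out[j, 1] -= fmag * dy
        force_out[j, 2] -= fmag * dz

    for c_ in range(N_COMPONENTS):
        comps[c_] *= rescale
    for k in range(n):
        if frozen[k]:
            force_out[k, 0] = 0.0
            force_out[k, 1] = 0.0
            force_out[k, 2] = 0.0
        else:
            force_out[k, 0] *= rescale
            force_out[k, 1] *= rescale
            force_out[k, 2] *= rescale
    return comps


@njit(cache=True)
def drms_value_grad(pos, bi, bj, bsigma, grad_out):
    """dRMS over binding contacts and its gradient."""
    n = bi.shape[0]
    for k in range(grad_out.shape[0]):
        grad_out[k, 0] = 0.0
        grad_out[k, 1] = 0.0
        grad_out[k, 2] = 0.0
    ssq = 0.0
    for c in range(n):
        i = bi[c]
        j = bj[c]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        ssq += (r - bsigma[c]) ** 2
    drms = np.sqrt(ssq / n)
    if drms < 1.0e-12:
        return drms
    for c in range(n):
        i = bi[c]
        j = bj[c]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        coef = (r - bsigma[c]) / (n * drms * r)
        grad_out[i, 0] += coef * dx
        grad_out[i, 1] += coef * dy
        grad_out[i, 2] += coef * dz
        grad_out[j, 0] -= coef * dx
        grad_out[j, 1] -= coef * dy
        grad_out[j, 2] -= coef * dz
    return drms


@njit(cache=True)
def metad_bias(s, centers, heights, n_hills, width):
    v = 0.0
    for h in range(n_hills):
        d = s - centers[h]
        v += heights[h] * np.exp(-d * d / (2.0 * width * width))
    return v


@njit(cache=True)
def metad_bias_grad(s, centers, heights, n_hills, width):
    g = 0.0
    for h in range(n_hills):
        d = s - centers[h]
        g += heights[h] * np.exp(-d * d / (2.0 * width * width)) * (
            -d / (width * width)
        )
    return g


@njit(cache=True)
def run_md(
    pos, vel, frozen,
    bonds, bond_r0, k_bond,
    angles, angle_t0, k_angle,
    dihs, dih_p0, k_dih,
    ci, cj, csigma, ceps, cclass,
    ev_i, ev_j, ev_sigma,
    el_i, el_j, el_qq, dh_a, dh_lambda,
    rescale,
    n_steps, dt, gamma, kT, seed, record_every,
    bias_kind, bind_i, bind_j, bind_sigma,
    umb_center, umb_k,
    hill_height, hill_width, hill_stride, bias_factor,
    hill_centers, hill_heights, n_hills_in,
    target_lo, target_hi,
    conf_k, conf_r,
    adaptive_stride,
):
    """BAOAB Langevin dynamics with optional dRMS bias.

    Returns (frames_pos, frames_comps, frames_cv, frames_bias, n_hills,
    t_rescaled, reached, step_reached, diverged).
    ``hill_centers``/``hill_heights`` are in/out scratch arrays sized for the
    maximum hill count; ``n_hills_in`` hills are assumed already deposited.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n_frames = n_steps // record_every
    frames_pos = np.zeros((n_frames, n, 3))
    frames_comps = np.zeros((n_frames, N_COMPONENTS))
    frames_cv = np.zeros(n_frames)
    frames_bias = np.zeros(n_frames)

    force = np.zeros((n, 3))
    bias_grad = np.zeros((n, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)

    comps = forces_energy(
        pos, frozen, bonds, bond_r0, k_bond, angles, angle_t0, k_angle,
        dihs, dih_p0, k_dih, ci, cj, csigma, ceps, cclass,
        ev_i, ev_j, ev_sigma, el_i, el_j, el_qq, dh_a, dh_lambda,
        rescale, force,
    )
    n_hills = n_hills_in
    stride = hill_stride
    t_rescaled = 0.0
    reached = 0
    step_reached = -1
    diverged = 0
    next_decade = 10.0

    for step in range(n_steps):
        # bias force on top of the physical force
        cv = 0.0
        vbias = 0.0
        if bias_kind != BIAS_NONE:
            cv = drms_value_grad(pos, bind_i, bind_j, bind_sigma, bias_grad)
            if bias_kind == BIAS_UMBRELLA:
                vbias = 0.5 * umb_k * (cv - umb_center) ** 2
                coef = -umb_k * (cv - umb_center)
            else:
                vbias = metad_bias(cv, hill_centers, hill_heights, n_hills, hill_width)
                coef = -metad_bias_grad(cv, hill_centers, hill_heights, n_hills, hill_width)
            for k in range(n):
                if not frozen[k]:
                    force[k, 0] += coef * bias_grad[k, 0]
                    force[k, 1] += coef * bias_grad[k, 1]
                    force[k, 2] += coef * bias_grad[k, 2]

        if conf_k > 0.0:
            for k in range(n):
                if frozen[k]:
                    continue
                d = np.sqrt(pos[k, 0] ** 2 + pos[k, 1] ** 2 + pos[k, 2] ** 2)
                if d > conf_r:
                    cc = -conf_k * (d - conf_r) / d
                    force[k, 0] += cc * pos[k, 0]
                    force[k, 1] += cc * pos[k, 1]
                    force[k, 2] += cc * pos[k, 2]

        # B A O A B
        for k in range(n):
            if frozen[k]:
                continue
            for d3 in range(3):
                vel[k, d3] += 0.5 * dt * force[k, d3]
                pos[k, d3] += 0.5 * dt * vel[k, d3]
        for k in range(n):
            if frozen[k]:
                continue
            for d3 in range(3):
                vel[k, d3] = c1 * vel[k, d3] + c2 * np.random.standard_normal()
                pos[k, d3] += 0.5 * dt * vel[k, d3]
        comps = forces_energy(
            pos, frozen, bonds, bond_r0, k_bond, angles, angle_t0, k_angle,
            dihs, dih_p0, k_dih, ci, cj, csigma, ceps, cclass,
            ev_i, ev_j, ev_sigma, el_i, el_j, el_qq, dh_a, dh_lambda,
            rescale, force,
        )
        etot = 0.0
        for c_ in range(N_COMPONENTS):
            etot += comps[c_]
        if np.abs(etot) > _ENERGY_GUARD or np.isnan(etot):
            diverged = 1
            break
        if bias_kind != BIAS_NONE:
            cv = drms_value_grad(pos, bind_i, bind_j, bind_sigma, bias_grad)
            if bias_kind == BIAS_UMBRELLA:
                vbias = 0.5 * umb_k * (cv - umb_center) ** 2
                coef = -umb_k * (cv - umb_center)
            else:
                vbias = metad_bias(cv, hill_centers, hill_heights, n_hills, hill_width)
                coef = -metad_bias_grad(cv, hill_centers, hill_heights, n_hills, hill_width)
            for k in range(n):
                if not frozen[k]:
                    force[k, 0] += coef * bias_grad[k, 0]
                    force[k, 1] += coef * bias_grad[k, 1]
                    force[k, 2] += coef * bias_grad[k, 2]
        if conf_k > 0.0:
            for k in range(n):
                if frozen[k]:
                    continue
                d = np.sqrt(pos[k, 0] ** 2 + pos[k, 1] ** 2 + pos[k, 2] ** 2)
                if d > conf_r:
                    cc = -conf_k * (d - conf_r) / d
                    force[k, 0] += cc * pos[k, 0]
                    force[k, 1] += cc * pos[k, 1]
                    force[k, 2] += cc * pos[k, 2]
        for k in range(n):
            if frozen[k]:
                continue
            for d3 in range(3):
                vel[k, d3] += 0.5 * dt * force[k, d3]

        if bias_kind == BIAS_METAD:
            t_rescaled += dt * np.exp(vbias / kT)
            if hill_height > 0.0 and (step + 1) % stride == 0 and n_hills < hill_centers.shape[0]:
                wt = hill_height * np.exp(
                    -metad_bias(cv, hill_centers, hill_heights, n_hills, hill_width)
                    / ((bias_factor - 1.0) * kT)
                )
                hill_centers[n_hills] = cv
                hill_heights[n_hills] = wt
                n_hills += 1
            if adaptive_stride == 1 and step > 0:
                acc = t_rescaled / (dt * (step + 1))
                if acc >= next_decade:
                    stride *= 2
                    next_decade *= 10.0
            if target_lo <= cv <= target_hi:
                reached = 1
                step_reached = step + 1
                nf = (step + 1) // record_every
                frames_pos = frames_pos[:nf]
                frames_comps = frames_comps[:nf]
                frames_cv = frames_cv[:nf]
                frames_bias = frames_bias[:nf]
                break

        if (step + 1) % record_every == 0:
            f = (step + 1) // record_every - 1
            for k in range(n):
                frames_pos[f, k, 0] = pos[k, 0]
                frames_pos[f, k, 1] = pos[k, 1]
                frames_pos[f, k, 2] = pos[k, 2]
            for c_ in range(N_COMPONENTS):
                frames_comps[f, c_] = comps[c_]
            if bias_kind != BIAS_NONE or bind_i.shape[0] > 0:
                frames_cv[f] = drms_value_grad(pos, bind_i, bind_j, bind_sigma, bias_grad)
            frames_bias[f] = vbias

    return (
        frames_pos, frames_comps, frames_cv, frames_bias,
        n_hills, t_rescaled, reached, step_reached, diverged,
    )


# ---------------------------------------------------------------------------
# one-dimensional reference dynamics (quartic double well)


@njit(cache=True)
def run_1d(
    x0, n_steps, dt, gamma, kT, seed, record_every,
    barrier,
    bias_kind, umb_center, umb_k,
    hill_height, hill_width, hill_stride, bias_factor,
    hill_centers, hill_heights, n_hills_in,
    target_lo, target_hi,
    adaptive_stride,
):
    """Underdamped BAOAB on V(x) = barrier * (x^2 - 1)^2, with optional bias.

    Returns (xs, vbias_series, n_hills, t_rescaled, reached, step_reached).
    """
    np.random.seed(seed)
    n_frames = n_steps // record_every
    xs = np.zeros(n_frames)
    vb_series = np.zeros(n_frames)
    x = x0
    v = 0.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    n_hills = n_hills_in
    stride = hill_stride
    t_rescaled = 0.0
    reached = 0
    step_reached = -1
    next_decade = 10.0

    def grad(xx):
        return 4.0 * barrier * xx * (xx * xx - 1.0)

    f = -grad(x)
    vbias = 0.0
    if bias_kind == BIAS_UMBRELLA:
        f += -umb_k * (x - umb_center)
    elif bias_kind == BIAS_METAD:
        f += -metad_bias_grad(x, hill_centers, hill_heights, n_hills, hill_width)

    for step in range(n_steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.standard_normal()
        x += 0.5 * dt * v
        f = -grad(x)
        vbias = 0.0
        if bias_kind == BIAS_UMBRELLA:
            vbias = 0.5 * umb_k * (x - umb_center) ** 2
            f += -umb_k * (x - umb_center)
        elif bias_kind == BIAS_METAD:
            vbias = metad_bias(x, hill_centers, hill_heights, n_hills, hill_width)
            f += -metad_bias_grad(x, hill_centers, hill_heights, n_hills, hill_width)
        v += 0.5 * dt * f

        if bias_kind == BIAS_METAD:
            t_rescaled += dt * np.exp(vbias / kT)
            if hill_height > 0.0 and (step + 1) % stride == 0 and n_hills < hill_centers.shape[0]:
                wt = hill_height * np.exp(
                    -metad_bias(x, hill_centers, hill_heights, n_hills, hill_width)
                    / ((bias_factor - 1.0) * kT)
                )
                hill_centers[n_hills] = x
                hill_heights[n_hills] = wt
                n_hills += 1
            if adaptive_stride == 1:
                acc = t_rescaled / (dt * (step + 1))
                if acc >= next_decade:
                    stride *= 2
                    next_decade *= 10.0
        if target_lo <= x <= target_hi:
            reached = 1
            step_reached = step + 1
            nf = (step + 1) // record_every
            xs = xs[:nf]
            vb_series = vb_series[:nf]
            break
        if (step + 1) % record_every == 0:
            fr = (step + 1) // record_every - 1
            xs[fr] = x
            vb_series[fr] = vbias
    return xs, vb_series, n_hills, t_rescaled, reached, step_reached
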