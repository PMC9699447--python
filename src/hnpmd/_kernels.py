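"""Compiled numerical kernels: analytic forces and the velocity-Verlet loop.

Everything here works on bare arrays so numba can compile it once and the
integrator can advance 1e5+ steps without touching Python objects.  Energies
and forces are in kcal/mol and kcal/(mol nm); the MD loop converts to
kJ-based accelerations internally (1 g/mol * (nm/ps)^2 = 1 kJ/mol).
"""

from __future__ import annotations

import numpy as np
from numba import njit

KCAL_TO_KJ = 4.184


@njit(cache=True, fastmath=False)
def forces_and_energies(pos, cls, l0, kd, theta0, ktheta, kphi,
                        sigma, rc, eps_mat, lam_mat, shift_mat):
    """Analytic forces plus the four energy terms for one configuration.

    Returns (forces[N,3], e_stretch, e_bend, e_torsion, e_nonbonded, min_r2)
    where min_r2 is the smallest squared nonbonded pair distance encountered
    (for overlap detection by the caller).
    """
    n = pos.shape[0]
    f = np.zeros((n, 3))
    e_stretch = 0.0
    e_bend = 0.0
    e_torsion = 0.0
    e_nb = 0.0
    min_r2 = 1e30

    # bonds: (kd/2)(l - l0)^2
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = r - l0
        e_stretch += 0.5 * kd * dl * dl
        if r > 1e-12:
            coef = -kd * dl / r
            f[i + 1, 0] += coef * dx
            f[i + 1, 1] += coef * dy
            f[i + 1, 2] += coef * dz
            f[i, 0] -= coef * dx
            f[i, 1] -= coef * dy
            f[i, 2] -= coef * dz

    # angles between consecutive bond vectors: (ktheta/2)(theta - theta0)^2
    for i in range(n - 2):
        # atoms a=i, b=i+1, c=i+2; u = rb - ra, v = rc - rb
        ux = pos[i + 1, 0] - pos[i, 0]
        uy = pos[i + 1, 1] - pos[i, 1]
        uz = pos[i + 1, 2] - pos[i, 2]
        vx = pos[i + 2, 0] - pos[i + 1, 0]
        vy = pos[i + 2, 1] - pos[i + 1, 1]
        vz = pos[i + 2, 2] - pos[i + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if nu < 1e-12 or nv < 1e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - theta0
        e_bend += 0.5 * ktheta * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        # dE/dcos = -ktheta * dth / sin(theta)
        decos = -ktheta * dth / s
        # dcos/du and dcos/dv
        dcux = vx / (nu * nv) - c * ux / (nu * nu)
        dcuy = vy / (nu * nv) - c * uy / (nu * nu)
        dcuz = vz / (nu * nv) - c * uz / (nu * nu)
        dcvx = ux / (nu * nv) - c * vx / (nv * nv)
        dcvy = uy / (nu * nv) - c * vy / (nv * nv)
        dcvz = uz / (nu * nv) - c * vz / (nv * nv)
        # F = -dE/dr ; du/dra = -1, dv/drc = +1
        f[i, 0] += decos * dcux
        f[i, 1] += decos * dcuy
        f[i, 2] += decos * dcuz
        f[i + 1, 0] -= decos * (dcux - dcvx)
        f[i + 1, 1] -= decos * (dcuy - dcvy)
        f[i + 1, 2] -= decos * (dcuz - dcvz)
        f[i + 2, 0] -= decos * dcvx
        f[i + 2, 1] -= decos * dcvy
        f[i + 2, 2] -= decos * dcvz

    # dihedrals: (kphi/2)(1 - cos 3 phi), phi measured from trans.
    # Internally phi_std (trans at +/-pi) is used: the energy equals
    # (kphi/2)(1 + cos 3 phi_std) and dE/dphi_std = -(3/2) kphi sin(3 phi_std).
    for i in range(n - 3):
        b1x = pos[i + 1, 0] - pos[i, 0]
        b1y = pos[i + 1, 1] - pos[i, 1]
        b1z = pos[i + 1, 2] - pos[i, 2]
        b2x = pos[i + 2, 0] - pos[i + 1, 0]
        b2y = pos[i + 2, 1] - pos[i + 1, 1]
        b2z = pos[i + 2, 2] - pos[i + 1, 2]
        b3x = pos[i + 3, 0] - pos[i + 2, 0]
        b3y = pos[i + 3, 1] - pos[i + 2, 1]
        b3z = pos[i + 3, 2] - pos[i + 2, 2]
        # n1 = b1 x b2, n2 = b2 x b3
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-18 or n2sq < 1e-18 or b2n < 1e-12:
            # collinear triple: phi defined as trans, zero energy and force
            continue
        # phi_std = atan2(((n1 x n2) . b2hat), n1 . n2)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        yval = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
        xval = n1x * n2x + n1y * n2y + n1z * n2z
        phi_std = np.arctan2(yval, xval)
        e_torsion += 0.5 * kphi * (1.0 + np.cos(3.0 * phi_std))
        dedphi = -1.5 * kphi * np.sin(3.0 * phi_std)
        # dphi/dr for the four atoms
        g0 = -b2n / n1sq
        g3 = b2n / n2sq
        d0x = g0 * n1x
        d0y = g0 * n1y
        d0z = g0 * n1z
        d3x = g3 * n2x
        d3y = g3 * n2y
        d3z = g3 * n2z
        t1 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        t3 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        d1x = -(1.0 + t1) * d0x + t3 * d3x
        d1y = -(1.0 + t1) * d0y + t3 * d3y
        d1z = -(1.0 + t1) * d0z + t3 * d3z
        d2x = t1 * d0x - (1.0 + t3) * d3x
        d2y = t1 * d0y - (1.0 + t3) * d3y
        d2z = t1 * d0z - (1.0 + t3) * d3z
        f[i, 0] -= dedphi * d0x
        f[i, 1] -= dedphi * d0y
        f[i, 2] -= dedphi * d0z
        f[i + 1, 0] -= dedphi * d1x
        f[i + 1, 1] -= dedphi * d1y
        f[i + 1, 2] -= dedphi * d1z
        f[i + 2, 0] -= dedphi * d2x
        f[i + 2, 1] -= dedphi * d2y
        f[i + 2, 2] -= dedphi * d2z
        f[i + 3, 0] -= dedphi * d3x
        f[i + 3, 1] -= dedphi * d3y
        f[i + 3, 2] -= dedphi * d3z

    # nonbonded: truncated-and-shifted 12-6 LJ, pairs with j - i >= 4
    rc2 = rc * rc
    sig2 = sigma * sigma
    for i in range(n - 4):
        ci = cls[i]
        for j in range(i + 4, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < min_r2:
                min_r2 = r2
            if r2 > rc2 or r2 < 1e-16:
                continue
            cj = cls[j]
            eps4 = 4.0 * eps_mat[ci, cj]
            lam = lam_mat[ci, cj]
            sr2 = sig2 / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            e_nb += eps4 * (sr12 - lam * sr6) - shift_mat[ci, cj]
            coef = eps4 * (12.0 * sr12 - 6.0 * lam * sr6) / r2
            f[i, 0] += coef * dx
            f[i, 1] += coef * dy
            f[i, 2] += coef * dz
            f[j, 0] -= coef * dx
            f[j, 1] -= coef * dy
            f[j, 2] -= coef * dz

    return f, e_stretch, e_bend, e_torsion, e_nb, min_r2


@njit(cache=True)
def _kinetic_kj(vel, masses):
    ke = 0.0
    n = vel.shape[0]
    for i in range(n):
        ke += 0.5 * masses[i] * (vel[i, 0] * vel[i, 0] +
                                 vel[i, 1] * vel[i, 1] +
                                 vel[i, 2] * vel[i, 2])
    return ke


@njit(cache=True)
def _nose_hoover_half(vel, masses, xi, xi2, dt, kbt_nf_kj, kbt_kj, q1, q2):
    """Half-step Nose-Hoover chain (length 2) update.

    The primary friction xi couples to the kinetic energy, the secondary
    xi2 thermostats xi itself — the standard cure for the non-ergodic
    sampling a single thermostat gives stiff, nearly harmonic modes.
    Returns (xi, xi2).
    """
    ke2 = 2.0 * _kinetic_kj(vel, masses)
    xi2 += 0.25 * dt * (q1 * xi * xi - kbt_kj) / q2
    e8 = np.exp(-0.125 * dt * xi2)
    xi = xi * e8 * e8 + 0.25 * dt * (ke2 - kbt_nf_kj) / q1 * e8
    scale = np.exp(-0.5 * dt * xi)
    n = vel.shape[0]
    for i in range(n):
        vel[i, 0] *= scale
        vel[i, 1] *= scale
        vel[i, 2] *= scale
    ke2 = ke2 * scale * scale
    xi = xi * e8 * e8 + 0.25 * dt * (ke2 - kbt_nf_kj) / q1 * e8
    xi2 += 0.25 * dt * (q1 * xi * xi - kbt_kj) / q2
    return xi, xi2


@njit(cache=True)
def md_run(pos, vel, masses, cls,
           l0, kd, theta0, ktheta, kphi, sigma, rc,
           eps_mat, lam_mat, shift_mat,
           dt, n_steps, use_thermostat, kbt_nf_kj, kbt_kj, q1, q2, xi, xi2,
           stride, snap_pos, snap_vel, snap_energy):
    """Advance n_steps of (thermostatted) velocity Verlet in place.

    dt is in ps; kbt_nf_kj = n_free * kB * T and kbt_kj = kB * T, both in
    kJ/mol; q1/q2 are the chain coupling masses in kJ/mol ps^2.  Every
    ``stride`` steps the configuration is stored in snap_pos/snap_vel and
    its energy terms (stretch, bend, torsion, nonbonded, kinetic; kcal/mol)
    in snap_energy.

    Returns (xi, xi2, n_snapshots, status_step); status_step >= 0 flags the
    step at which non-finite coordinates appeared (run aborted there).
    """
    n = pos.shape[0]
    f, es, eb, et, enb, min_r2 = forces_and_energies(
        pos, cls, l0, kd, theta0, ktheta, kphi, sigma, rc,
        eps_mat, lam_mat, shift_mat)
    n_snap = 0
    for step in range(n_steps):
        if use_thermostat:
            xi, xi2 = _nose_hoover_half(vel, masses, xi, xi2, dt,
                                        kbt_nf_kj, kbt_kj, q1, q2)
        for i in range(n):
            a = 0.5 * dt * KCAL_TO_KJ / masses[i]
            vel[i, 0] += a * f[i, 0]
            vel[i, 1] += a * f[i, 1]
            vel[i, 2] += a * f[i, 2]
            pos[i, 0] += dt * vel[i, 0]
            pos[i, 1] += dt * vel[i, 1]
            pos[i, 2] += dt * vel[i, 2]
        f, es, eb, et, enb, min_r2 = forces_and_energies(
            pos, cls, l0, kd, theta0, ktheta, kphi, sigma, rc,
            eps_mat, lam_mat, shift_mat)
        if min_r2 < 1e-8 or not np.isfinite(es + enb):
            return xi, xi2, n_snap, step
        for i in range(n):
            a = 0.5 * dt * KCAL_TO_KJ / masses[i]
            vel[i, 0] += a * f[i, 0]
            vel[i, 1] += a * f[i, 1]
            vel[i, 2] += a * f[i, 2]
        if use_thermostat:
            xi, xi2 = _nose_hoover_half(vel, masses, xi, xi2, dt,
                                        kbt_nf_kj, kbt_kj, q1, q2)
        if (step + 1) % stride == 0 and n_snap < snap_pos.shape[0]:
            for i in range(n):
                snap_pos[n_snap, i, 0] = pos[i, 0]
                snap_pos[n_snap, i, 1] = pos[i, 1]
                snap_pos[n_snap, i, 2] = pos[i, 2]
                snap_vel[n_snap, i, 0] = vel[i, 0]
                snap_vel[n_snap, i, 1] = vel[i, 1]
                snap_vel[n_snap, i, 2] = vel[i, 2]
            snap_energy[n_snap, 0] = es
            snap_energy[n_snap, 1] = eb
            snap_energy[n_snap, 2] = et
            snap_energy[n_snap, 3] = enb
            snap_energy[n_snap, 4] = _kinetic_kj(vel, masses) / KCAL_TO_KJ
            n_snap += 1
    return xi, xi2, n_snap, -1
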