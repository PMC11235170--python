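"""Numba-accelerated inner loops for the Cα Go-model integrator.

The math here mirrors :func:`tandemrrm.gomodel.energy_forces` exactly; the
pure-numpy implementation remains the reference and the fallback when numba
is unavailable. Thermostat noise inside the jitted loop is drawn from
numpy's legacy global generator seeded per call, so trajectories are
deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def forces_nb(
    x,
    bond_r0,
    angle_t0,
    dihedral_p0,
    contacts,
    contact_sigma,
    noncontacts,
    kb,
    ka,
    kd1,
    kd3,
    eps,
    sigma0,
    f,
):
    n = x.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = 0.0

    # bonds
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[i]
        e += kb * dr * dr
        c = 2.0 * kb * dr / r
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[i + 1, 0] -= c * dx
        f[i + 1, 1] -= c * dy
        f[i + 1, 2] -= c * dz

    # angles
    for i in range(n - 2):
        ux = x[i, 0] - x[i + 1, 0]
        uy = x[i, 1] - x[i + 1, 1]
        uz = x[i, 2] - x[i + 1, 2]
        vx = x[i + 2, 0] - x[i + 1, 0]
        vy = x[i + 2, 1] - x[i + 1, 1]
        vz = x[i + 2, 2] - x[i + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        cos = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if cos > 1.0 - 1e-12:
            cos = 1.0 - 1e-12
        if cos < -1.0 + 1e-12:
            cos = -1.0 + 1e-12
        dtheta = np.arccos(cos) - angle_t0[i]
        e += ka * dtheta * dtheta
        pref = 2.0 * ka * dtheta / np.sqrt(1.0 - cos * cos)
        inv = 1.0 / (nu * nv)
        cu = cos / (nu * nu)
        cv = cos / (nv * nv)
        fix = pref * (vx * inv - cu * ux)
        fiy = pref * (vy * inv - cu * uy)
        fiz = pref * (vz * inv - cu * uz)
        fkx = pref * (ux * inv - cv * vx)
        fky = pref * (uy * inv - cv * vy)
        fkz = pref * (uz * inv - cv * vz)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[i + 2, 0] += fkx
        f[i + 2, 1] += fky
        f[i + 2, 2] += fkz
        f[i + 1, 0] -= fix + fkx
        f[i + 1, 1] -= fiy + fky
        f[i + 1, 2] -= fiz + fkz

    # dihedrals
    for i in range(n - 3):
        b1x = x[i + 1, 0] - x[i, 0]
        b1y = x[i + 1, 1] - x[i, 1]
        b1z = x[i + 1, 2] - x[i, 2]
        b2x = x[i + 2, 0] - x[i + 1, 0]
        b2y = x[i + 2, 1] - x[i + 1, 1]
        b2z = x[i + 2, 2] - x[i + 1, 2]
        b3x = x[i + 3, 0] - x[i + 2, 0]
        b3y = x[i + 3, 1] - x[i + 2, 1]
        b3z = x[i + 3, 2] - x[i + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = (n1y * b2z - n1z * b2y) / nb2
        my = (n1z * b2x - n1x * b2z) / nb2
        mz = (n1x * b2y - n1y * b2x) / nb2
        sy = mx * n2x + my * n2y + mz * n2z
        sx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sy, sx)
        dphi = phi - dihedral_p0[i]
        e += kd1 * (1.0 - np.cos(dphi)) + kd3 * (1.0 - np.cos(3.0 * dphi))
        dV = kd1 * np.sin(dphi) + 3.0 * kd3 * np.sin(3.0 * dphi)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        c1 = nb2 / n1sq
        c2 = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1sq * nb2)
        c3 = (b3x * b2x + b3y * b2y + b3z * b2z) / (n2sq * nb2)
        cl = nb2 / n2sq
        a1x, a1y, a1z = c1 * n1x, c1 * n1y, c1 * n1z
        a2x, a2y, a2z = c2 * n1x, c2 * n1y, c2 * n1z
        a3x, a3y, a3z = c3 * n2x, c3 * n2y, c3 * n2z
        dlx, dly, dlz = -cl * n2x, -cl * n2y, -cl * n2z
        f[i, 0] -= dV * a1x
        f[i, 1] -= dV * a1y
        f[i, 2] -= dV * a1z
        f[i + 1, 0] -= dV * (-a1x - a2x - a3x)
        f[i + 1, 1] -= dV * (-a1y - a2y - a3y)
        f[i + 1, 2] -= dV * (-a1z - a2z - a3z)
        f[i + 2, 0] -= dV * (-dlx + a2x + a3x)
        f[i + 2, 1] -= dV * (-dly + a2y + a3y)
        f[i + 2, 2] -= dV * (-dlz + a2z + a3z)
        f[i + 3, 0] -= dV * dlx
        f[i + 3, 1] -= dV * dly
        f[i + 3, 2] -= dV * dlz

    # 12-10 native contacts
    for k in range(contacts.shape[0]):
        i = contacts[k, 0]
        j = contacts[k, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        s2 = contact_sigma[k] * contact_sigma[k] / r2
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        e += eps * (5.0 * s12 - 6.0 * s10)
        c = -60.0 * eps * (s10 - s12) / r2
        f[i, 0] += c * dx
        f[i, 1] += c * dy
        f[i, 2] += c * dz
        f[j, 0] -= c * dx
        f[j, 1] -= c * dy
        f[j, 2] -= c * dz

    # truncated excluded volume
    s0sq = sigma0 * sigma0
    for k in range(noncontacts.shape[0]):
        i = noncontacts[k, 0]
        j = noncontacts[k, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < s0sq:
            s6 = (s0sq / r2) ** 3
            s12 = s6 * s6
            e += eps * (s12 - 2.0 * s6 + 1.0)
            c = 12.0 * eps * (s12 - s6) / r2
            f[i, 0] += c * dx
            f[i, 1] += c * dy
            f[i, 2] += c * dz
            f[j, 0] -= c * dx
            f[j, 1] -= c * dy
            f[j, 2] -= c * dz

    return e


@njit(cache=True)
def integrate_nb(
    x,
    v,
    bond_r0,
    angle_t0,
    dihedral_p0,
    contacts,
    contact_sigma,
    noncontacts,
    kb,
    ka,
    kd1,
    kd3,
    eps,
    sigma0,
    n_steps,
    dt,
    a_coef,
    b_coef,
    stride,
    seed,
    q_tol,
):
    """BAOAB Langevin loop; returns (E_pot, E_kin, Q) sampled at stride."""
    np.random.seed(seed)
    n = x.shape[0]
    f = np.zeros((n, 3))
    e = forces_nb(
        x, bond_r0, angle_t0, dihedral_p0, contacts, contact_sigma,
        noncontacts, kb, ka, kd1, kd3, eps, sigma0, f,
    )
    n_samples = n_steps // stride
    e_out = np.empty(n_samples)
    ke_out = np.empty(n_samples)
    q_out = np.empty(n_samples)
    m = 0
    for step in range(1, n_steps + 1):
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d]
                x[i, d] += 0.5 * dt * v[i, d]
        if b_coef > 0.0 or a_coef != 1.0:
            for i in range(n):
                for d in range(3):
                    v[i, d] = a_coef * v[i, d] + b_coef * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                x[i, d] += 0.5 * dt * v[i, d]
        e = forces_nb(
            x, bond_r0, angle_t0, dihedral_p0, contacts, contact_sigma,
            noncontacts, kb, ka, kd1, kd3, eps, sigma0, f,
        )
        for i in range(n):
            for d in range(3):
                v[i, d] += 0.5 * dt * f[i, d]
        if step % stride == 0:
            ke = 0.0
            for i in range(n):
                for d in range(3):
                    ke += 0.5 * v[i, d] * v[i, d]
            nq = 0
            for k in range(contacts.shape[0]):
                i = contacts[k, 0]
                j = contacts[k, 1]
                dx = x[i, 0] - x[j, 0]
                dy = x[i, 1] - x[j, 1]
                dz = x[i, 2] - x[j, 2]
                if np.sqrt(dx * dx + dy * dy + dz * dz) < q_tol * contact_sigma[k]:
                    nq += 1
            e_out[m] = e
            ke_out[m] = ke
            q_out[m] = nq / max(contacts.shape[0], 1)
            m += 1
    return e_out, ke_out, q_out
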