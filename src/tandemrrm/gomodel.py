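"""Cα structure-based (Go-type) folding model with WHAM thermal analysis.

A Clementi-style coarse-grained model: one bead per residue at the native Cα
position, harmonic bonds and angles at their native values, a 1+3 cosine
dihedral term, 12-10 Lennard-Jones wells for native contacts and a purely
repulsive r^-12 term for all other non-local pairs. Only native interactions
are attractive, so the energy landscape is funneled toward the input
structure and the folding temperature is read off the heat-capacity maximum
obtained by combining multi-temperature Langevin runs with the weighted
histogram analysis method (WHAM).

Everything is in reduced units (ε = k_B = 1, bead mass 1); temperatures are
unitless and lengths stay in Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    IntegrationError,
    TopologyError,
)
from .structcore import StructureModel

__all__ = [
    "GoSystem",
    "Trajectory",
    "ThermalScan",
    "FoldingCurve",
    "build_go_system",
    "potential_energy",
    "energy_forces",
    "fraction_native",
    "run_langevin",
    "run_scan",
    "wham",
    "folding_temperature",
]

CHAIN_BREAK_CUTOFF = 4.5   # Å, max tolerated native Cα-Cα step


@dataclass
class GoSystem:
    """Coarse-grained topology derived from a native structure."""

    coords0: np.ndarray            # (N, 3) native Cα positions, Å
    bond_r0: np.ndarray            # (N-1,) native bond lengths
    angle_t0: np.ndarray           # (N-2,) native angles, rad
    dihedral_p0: np.ndarray        # (N-3,) native dihedrals, rad
    contacts: np.ndarray           # (M, 2) residue index pairs, i < j
    contact_sigma: np.ndarray      # (M,) native Cα-Cα distances
    noncontacts: np.ndarray        # (P, 2) repulsive-only pairs
    k_bond: float = 100.0          # ε/Å²
    k_angle: float = 20.0          # ε/rad²
    k_dih1: float = 1.0            # ε
    k_dih3: float = 0.5            # ε
    epsilon: float = 1.0           # contact well depth, ε
    sigma0: float = 4.0            # excluded-volume radius, Å

    @property
    def n_beads(self) -> int:
        return self.coords0.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.contacts.shape[0]

    def with_extra_contact(self, i: int, j: int) -> "GoSystem":
        """Copy of the system with one additional native contact (i, j)."""
        i, j = sorted((int(i), int(j)))
        sigma = float(np.linalg.norm(self.coords0[i] - self.coords0[j]))
        contacts = np.vstack([self.contacts, [i, j]])
        sigmas = np.append(self.contact_sigma, sigma)
        keep = ~((self.noncontacts[:, 0] == i) & (self.noncontacts[:, 1] == j))
        return replace(
            self,
            contacts=contacts,
            contact_sigma=sigmas,
            noncontacts=self.noncontacts[keep],
        )


@dataclass
class Trajectory:
    """Sampled observables from one constant-temperature run."""

    temperature: float
    steps: np.ndarray
    energy: np.ndarray             # potential energy, reduced units
    q: np.ndarray                  # fraction of native contacts
    stride: int
    seed: int
    equilibration: int = 0         # leading samples to discard in analysis

    def production(self) -> tuple[np.ndarray, np.ndarray]:
        return self.energy[self.equilibration:], self.q[self.equilibration:]


@dataclass
class ThermalScan:
    """Trajectories at distinct temperatures feeding WHAM."""

    trajectories: list[Trajectory]

    def __post_init__(self) -> None:
        temps = [t.temperature for t in self.trajectories]
        if len(set(temps)) != len(temps):
            raise InputError("scan temperatures must be distinct")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t.temperature for t in self.trajectories])


@dataclass
class FoldingCurve:
    """WHAM output: heat capacity on a temperature grid."""

    t_grid: np.ndarray
    cv: np.ndarray
    mean_energy: np.ndarray
    free_energies: np.ndarray      # per window, up to a constant
    converged: bool
    residual: float
    t_fold: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# Topology construction

def build_go_system(
    model: StructureModel,
    contact_cutoff: float = 4.5,
    min_separation: int = 3,
    chain: str | None = None,
    **force_constants,
) -> GoSystem:
    """Build the Cα topology from a structure.

    A native contact (i, j) is included when any heavy-atom pair between
    residues i and j lies within ``contact_cutoff`` Å and the sequence
    separation |i - j| is at least ``min_separation``; the contact's native
    length is the Cα-Cα distance. All other pairs with |i - j| >=
    ``min_separation`` interact through excluded volume only.
    """
    if contact_cutoff <= 0 or min_separation < 1:
        raise ConfigurationError("invalid contact-map parameters")
    resnums = model.residue_numbers(chain)
    n = len(resnums)
    if n < 4:
        raise InputError("need at least 4 residues")
    ca = model.ca_coords(resnums, chain)

    steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    if np.any(steps > CHAIN_BREAK_CUTOFF):
        k = int(np.argmax(steps > CHAIN_BREAK_CUTOFF))
        raise TopologyError(
            f"chain break between residues {resnums[k]} and {resnums[k + 1]} "
            f"(Cα-Cα {steps[k]:.2f} Å)"
        )

    # heavy-atom groups per residue for the contact scan
    groups = []
    index_of = {r: k for k, r in enumerate(resnums)}
    per_res: dict[int, list[int]] = {r: [] for r in resnums}
    for i, (c, r, e) in enumerate(zip(model.chain, model.resnum, model.element)):
        if chain is not None and c != chain:
            continue
        if e in ("H", "D") or int(r) not in per_res:
            continue
        per_res[int(r)].append(i)
    groups = [model.coords[per_res[r]] for r in resnums]

    contacts = []
    sigmas = []
    noncon = []
    for i in range(n):
        for j in range(i + min_separation, n):
            dmin = np.min(
                np.linalg.norm(
                    groups[i][:, None, :] - groups[j][None, :, :], axis=-1
                )
            )
            if dmin <= contact_cutoff:
                contacts.append((i, j))
                sigmas.append(float(np.linalg.norm(ca[i] - ca[j])))
            else:
                noncon.append((i, j))

    b = ca[1:] - ca[:-1]
    angle_t0 = _angles(ca)
    dihedral_p0 = _dihedrals(ca)
    return GoSystem(
        coords0=ca,
        bond_r0=np.linalg.norm(b, axis=1),
        angle_t0=angle_t0,
        dihedral_p0=dihedral_p0,
        contacts=np.array(contacts, dtype=int).reshape(-1, 2),
        contact_sigma=np.array(sigmas),
        noncontacts=np.array(noncon, dtype=int).reshape(-1, 2),
        **force_constants,
    )


def _angles(x: np.ndarray) -> np.ndarray:
    u = x[:-2] - x[1:-1]
    v = x[2:] - x[1:-1]
    cos = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.arccos(np.clip(cos, -1.0, 1.0))


def _dihedrals(x: np.ndarray) -> np.ndarray:
    b1 = x[1:-2] - x[:-3]
    b2 = x[2:-1] - x[1:-2]
    b3 = x[3:] - x[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
    return np.arctan2(
        np.einsum("ij,ij->i", m, n2), np.einsum("ij,ij->i", n1, n2)
    )


# ---------------------------------------------------------------------------
# Energy and forces (vectorized)

def energy_forces(x: np.ndarray, sys: GoSystem) -> tuple[float, np.ndarray]:
    """Potential energy and forces at configuration ``x``."""
    n = x.shape[0]
    f = np.zeros_like(x)
    e = 0.0

    # bonds (b is reused by the angle and dihedral terms)
    b = x[1:] - x[:-1]
    r = np.sqrt(np.einsum("ij,ij->i", b, b))
    dr = r - sys.bond_r0
    e += sys.k_bond * float(dr @ dr)
    fb = (2.0 * sys.k_bond * dr / r)[:, None] * b
    f[:-1] += fb
    f[1:] -= fb

    # angles: u, v point from the vertex bead outwards
    u = -b[:-1]
    v = b[1:]
    nu, nv = r[:-1], r[1:]
    cos = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1 + 1e-12, 1 - 1e-12)
    dtheta = np.arccos(cos) - sys.angle_t0
    e += sys.k_angle * float(dtheta @ dtheta)
    pref = (2.0 * sys.k_angle * dtheta / np.sqrt(1.0 - cos**2))[:, None]
    fi = pref * (v / (nu * nv)[:, None] - (cos / nu**2)[:, None] * u)
    fk = pref * (u / (nu * nv)[:, None] - (cos / nv**2)[:, None] * v)
    f[:-2] += fi
    f[2:] += fk
    f[1:-1] -= fi + fk

    # dihedrals (Blondel-Karplus analytic torsion gradient)
    if n >= 4:
        b1, b2, b3 = b[:-2], b[1:-1], b[2:]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = r[1:-1]
        phi = np.arctan2(
            np.einsum("ij,ij->i", np.cross(n1, b2 / nb2[:, None]), n2),
            np.einsum("ij,ij->i", n1, n2),
        )
        dphi = phi - sys.dihedral_p0
        e += float(
            np.sum(
                sys.k_dih1 * (1.0 - np.cos(dphi))
                + sys.k_dih3 * (1.0 - np.cos(3.0 * dphi))
            )
        )
        dV = (sys.k_dih1 * np.sin(dphi) + 3.0 * sys.k_dih3 * np.sin(3.0 * dphi))[
            :, None
        ]
        n1sq = np.einsum("ij,ij->i", n1, n1)
        n2sq = np.einsum("ij,ij->i", n2, n2)
        a1 = (nb2 / n1sq)[:, None] * n1
        a2 = (np.einsum("ij,ij->i", b1, b2) / (n1sq * nb2))[:, None] * n1
        a3 = (np.einsum("ij,ij->i", b3, b2) / (n2sq * nb2))[:, None] * n2
        dphi_dl = -(nb2 / n2sq)[:, None] * n2
        f[:-3] -= dV * a1
        f[1:-2] -= dV * (-a1 - a2 - a3)
        f[2:-1] -= dV * (-dphi_dl + a2 + a3)
        f[3:] -= dV * dphi_dl

    # native contacts: 12-10 Lennard-Jones well of depth ε at r = σ_ij
    if sys.n_contacts:
        ci, cj = sys.contacts[:, 0], sys.contacts[:, 1]
        d = x[ci] - x[cj]
        rc = np.sqrt(np.einsum("ij,ij->i", d, d))
        s = sys.contact_sigma / rc
        s10 = s**10
        s12 = s10 * s * s
        e += sys.epsilon * float(np.sum(5.0 * s12 - 6.0 * s10))
        # dE/dr = 60 ε (s^10 - s^12)/r
        fv = (-60.0 * sys.epsilon * (s10 - s12) / rc**2)[:, None] * d
        f[:, 0] += np.bincount(ci, fv[:, 0], n) - np.bincount(cj, fv[:, 0], n)
        f[:, 1] += np.bincount(ci, fv[:, 1], n) - np.bincount(cj, fv[:, 1], n)
        f[:, 2] += np.bincount(ci, fv[:, 2], n) - np.bincount(cj, fv[:, 2], n)

    # excluded volume on the remaining non-local pairs (WCA-style: smoothly
    # truncated at r = σ0, so it vanishes — with zero force — at the native
    # state, where every non-contact pair is farther than σ0 by construction)
    if len(sys.noncontacts):
        ni, nj = sys.noncontacts[:, 0], sys.noncontacts[:, 1]
        d = x[ni] - x[nj]
        r2 = np.einsum("ij,ij->i", d, d)
        inside = r2 < sys.sigma0**2
        if np.any(inside):
            d = d[inside]
            r2 = r2[inside]
            s6 = (sys.sigma0**2 / r2) ** 3
            s12 = s6 * s6
            e += sys.epsilon * float(np.sum(s12 - 2.0 * s6 + 1.0))
            fv = (12.0 * sys.epsilon * (s12 - s6) / r2)[:, None] * d
            nii, njj = ni[inside], nj[inside]
            f[:, 0] += np.bincount(nii, fv[:, 0], n) - np.bincount(njj, fv[:, 0], n)
            f[:, 1] += np.bincount(nii, fv[:, 1], n) - np.bincount(njj, fv[:, 1], n)
            f[:, 2] += np.bincount(nii, fv[:, 2], n) - np.bincount(njj, fv[:, 2], n)

    return float(e), f


def potential_energy(x: np.ndarray, sys: GoSystem) -> float:
    return energy_forces(x, sys)[0]


def fraction_native(
    x: np.ndarray, sys: GoSystem, tolerance: float = 1.2
) -> float:
    """Fraction of native contacts formed: r_ij < tolerance × σ_ij."""
    if x.shape != sys.coords0.shape:
        raise InputError("frame size does not match system")
    if sys.n_contacts == 0:
        return 0.0
    r = np.linalg.norm(x[sys.contacts[:, 0]] - x[sys.contacts[:, 1]], axis=1)
    return float(np.mean(r < tolerance * sys.contact_sigma))


# ---------------------------------------------------------------------------
# Langevin dynamics

def run_langevin(
    sys: GoSystem,
    temperature: float,
    n_steps: int,
    dt: float = 0.005,
    friction: float = 1.0,
    seed: int = 0,
    stride: int = 100,
    x0: np.ndarray | None = None,
    energy_limit: float = 1e8,
) -> Trajectory:
    """Langevin leapfrog integration at constant reduced temperature.

    With ``friction=0`` and ``temperature=0`` the integrator reduces to
    plain (microcanonical) leapfrog, which is the energy-conservation check
    mode. Deterministic given ``seed``.
    """
    omega_max = math.sqrt(2.0 * sys.k_bond)      # stiffest bond, mass 1
    if dt * omega_max > 0.5:
        raise ConfigurationError(
            f"dt={dt} unstable for k_bond={sys.k_bond} (dt*omega={dt * omega_max:.2f} > 0.5)"
        )
    rng = np.random.default_rng(seed)
    x = np.array(sys.coords0 if x0 is None else x0, dtype=float)
    v = np.zeros_like(x)
    if temperature > 0:
        v = rng.normal(scale=math.sqrt(temperature), size=x.shape)

    if friction > 0:
        a = math.exp(-friction * dt)
        b = math.sqrt(temperature * (1.0 - a * a))
    else:
        a, b = 1.0, 0.0

    from . import _kernels

    if _kernels.HAVE_NUMBA:
        kernel_seed = int(rng.integers(2**31 - 1))
        e_out, _, q_out = _kernels.integrate_nb(
            x, v,
            sys.bond_r0, sys.angle_t0, sys.dihedral_p0,
            sys.contacts, sys.contact_sigma, sys.noncontacts,
            sys.k_bond, sys.k_angle, sys.k_dih1, sys.k_dih3,
            sys.epsilon, sys.sigma0,
            n_steps, dt, a, b, stride, kernel_seed, 1.2,
        )
        bad = ~np.isfinite(e_out) | (np.abs(e_out) > energy_limit)
        if np.any(bad):
            raise IntegrationError(
                f"energy diverged at step {(int(np.argmax(bad)) + 1) * stride}"
            )
        return Trajectory(
            temperature=temperature,
            steps=stride * np.arange(1, len(e_out) + 1),
            energy=e_out,
            q=q_out,
            stride=stride,
            seed=seed,
        )

    n_samples = n_steps // stride
    steps_out = np.empty(n_samples, dtype=int)
    e_out = np.empty(n_samples)
    q_out = np.empty(n_samples)

    e, f = energy_forces(x, sys)
    k = 0
    for step in range(1, n_steps + 1):
        # BAOAB-style splitting: kick, drift-half, thermostat, drift-half
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        if friction > 0:
            v = a * v + b * rng.normal(size=x.shape)
        x += 0.5 * dt * v
        e, f = energy_forces(x, sys)
        v += 0.5 * dt * f
        if step % stride == 0:
            if not math.isfinite(e) or abs(e) > energy_limit:
                raise IntegrationError(
                    f"energy diverged at step {step} (E={e:.3g})"
                )
            steps_out[k] = step
            e_out[k] = e
            q_out[k] = fraction_native(x, sys)
            k += 1
    return Trajectory(
        temperature=temperature,
        steps=steps_out,
        energy=e_out,
        q=q_out,
        stride=stride,
        seed=seed,
    )


def kinetic_series(
    sys: GoSystem,
    n_steps: int,
    dt: float = 0.005,
    seed: int = 0,
    stride: int = 10,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Microcanonical (NVE) run returning total-energy and potential series.

    Used for the energy-conservation check: velocity-Verlet with the
    thermostat off.
    """
    x = np.array(sys.coords0 if x0 is None else x0, dtype=float)
    v = np.zeros_like(x) if v0 is None else np.array(v0, dtype=float)

    from . import _kernels

    if _kernels.HAVE_NUMBA:
        e_out, ke_out, _ = _kernels.integrate_nb(
            x, v,
            sys.bond_r0, sys.angle_t0, sys.dihedral_p0,
            sys.contacts, sys.contact_sigma, sys.noncontacts,
            sys.k_bond, sys.k_angle, sys.k_dih1, sys.k_dih3,
            sys.epsilon, sys.sigma0,
            n_steps, dt, 1.0, 0.0, stride, seed, 1.2,
        )
        return e_out + ke_out, e_out

    e, f = energy_forces(x, sys)
    tot = []
    pot = []
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * f
        x += dt * v
        e, f = energy_forces(x, sys)
        v += 0.5 * dt * f
        if step % stride == 0:
            ke = 0.5 * float(np.sum(v * v))
            tot.append(e + ke)
            pot.append(e)
    return np.array(tot), np.array(pot)


def run_scan(
    sys: GoSystem,
    temperatures,
    n_steps: int,
    seed: int = 0,
    equilibration_fraction: float = 0.2,
    **kwargs,
) -> ThermalScan:
    """Independent runs over a temperature ladder (window seeds = seed + k)."""
    trajs = []
    for k, t in enumerate(temperatures):
        tr = run_langevin(sys, float(t), n_steps, seed=seed + k, **kwargs)
        tr.equilibration = int(equilibration_fraction * len(tr.energy))
        trajs.append(tr)
    return ThermalScan(trajectories=trajs)


# ---------------------------------------------------------------------------
# WHAM

def histogram_overlap(scan: ThermalScan) -> float:
    """Smallest overlap coefficient between adjacent-temperature histograms."""
    trajs = sorted(scan.trajectories, key=lambda t: t.temperature)
    lo = min(t.production()[0].min() for t in trajs)
    hi = max(t.production()[0].max() for t in trajs)
    edges = np.linspace(lo, hi, 101)
    hists = [
        np.histogram(t.production()[0], bins=edges, density=False)[0]
        / len(t.production()[0])
        for t in trajs
    ]
    overlaps = [
        float(np.minimum(hists[k], hists[k + 1]).sum())
        for k in range(len(hists) - 1)
    ]
    return min(overlaps) if overlaps else 1.0


def wham(
    scan: ThermalScan,
    n_bins: int = 100,
    tolerance: float = 1e-7,
    max_iterations: int = 100_000,
    t_grid: np.ndarray | None = None,
    energies: list[np.ndarray] | None = None,
    temperatures: np.ndarray | None = None,
) -> FoldingCurve:
    """Weighted histogram analysis over a multi-temperature scan.

    Solves the self-consistent WHAM equations for the density of states on
    an energy histogram pooled across windows, then evaluates ⟨E⟩(T) and
    C_v(T) = (⟨E²⟩ − ⟨E⟩²)/T² on a fine temperature grid. Accepts raw
    ``energies``/``temperatures`` arrays directly for oracle-driven use.
    """
    if energies is None:
        trajs = sorted(scan.trajectories, key=lambda t: t.temperature)
        energies = [t.production()[0] for t in trajs]
        temperatures = np.array([t.temperature for t in trajs])
        if len(trajs) > 1 and histogram_overlap(scan) <= 0.0:
            raise DegenerateInputError(
                "no energy-histogram overlap between adjacent temperatures"
            )
    temperatures = np.asarray(temperatures, dtype=float)
    betas = 1.0 / temperatures
    k_windows = len(energies)

    lo = min(e.min() for e in energies)
    hi = max(e.max() for e in energies)
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi + 1e-9, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros((k_windows, n_bins))
    for k, e in enumerate(energies):
        counts[k] = np.histogram(e, bins=edges)[0]
    n_k = counts.sum(axis=1)
    total = counts.sum(axis=0)

    # iterate: ln Ω(E) and window free energies f_k (dimensionless)
    f = np.zeros(k_windows)
    log_nk = np.log(n_k)
    be = betas[:, None] * centers[None, :]        # (K, B)
    occupied = total > 0
    residual = np.inf
    converged = False
    for _ in range(max_iterations):
        # ln denominator(E) = ln Σ_k N_k exp(f_k - β_k E)
        a = (f + log_nk)[:, None] - be
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        with np.errstate(divide="ignore"):
            log_omega = np.where(occupied, np.log(total) - log_den, -np.inf)
        # f_k = -ln Σ_E Ω(E) exp(-β_k E)
        g = log_omega[None, :] - be
        gmax = g.max(axis=1)
        f_new = -(gmax + np.log(np.exp(g - gmax[:, None]).sum(axis=1)))
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tolerance:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(f"WHAM did not converge (residual {residual:.2e})")

    if t_grid is None:
        t_grid = np.linspace(temperatures.min(), temperatures.max(), 400)
    t_grid = np.asarray(t_grid, dtype=float)
    cv = np.empty_like(t_grid)
    emean = np.empty_like(t_grid)
    lw = np.where(occupied, log_omega, -np.inf)
    for m, t in enumerate(t_grid):
        w = lw - centers / t
        wmax = w[occupied].max()
        p = np.exp(w - wmax)
        p /= p.sum()
        e1 = float(np.sum(p * centers))
        e2 = float(np.sum(p * centers**2))
        emean[m] = e1
        cv[m] = max((e2 - e1 * e1) / t**2, 0.0)
    return FoldingCurve(
        t_grid=t_grid,
        cv=cv,
        mean_energy=emean,
        free_energies=f,
        converged=converged,
        residual=residual,
    )


def folding_temperature(curve: FoldingCurve) -> float:
    """Heat-capacity maximum, refined by local quadratic interpolation."""
    i = int(np.argmax(curve.cv))
    if i == 0 or i == len(curve.cv) - 1:
        import warnings

        warnings.warn("C_v maximum at grid boundary; scan range too narrow")
        curve.t_fold = float(curve.t_grid[i])
        return curve.t_fold
    x = curve.t_grid[i - 1:i + 2]
    y = curve.cv[i - 1:i + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom >= 0:
        tf = float(x[1])
    else:
        tf = float(x[1] - 0.5 * (x[2] - x[1]) * (y[2] - y[0]) / denom)
    curve.t_fold = tf
    return tf
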