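"""¹⁵N CPMG relaxation-dispersion analysis.

Converts peak amplitudes measured under a constant-time CPMG element into
effective transverse relaxation rates R2,eff(ν_CPMG) = −ln[I(ν)/I₀]/T_rlx,
propagates replicate-based amplitude errors, flags residues with significant
exchange (Rex > 1.65 σ_Rex, one-sided 95% confidence), and fits flagged
profiles with two-state exchange models:

* fast limit (Luz-Meiboom):
  R2,eff(ν) = R2° + (Φ_ex/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/(4ν))],
  with Φ_ex = p_a·p_b·Δω² the composite amplitude (p_b and Δω are not
  separately identifiable in this regime);
* slow limit (Tollinger-Kay):
  R2,eff(ν) = R2° + k_ab·[1 − sinc(Δω/(4ν))].

A numerical two-site Bloch-McConnell propagator of the full echo train
serves as the general forward model and as the internal oracle for both
analytic limits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FitError, InputError

__all__ = [
    "DispersionDataset",
    "DispersionProfile",
    "RexResult",
    "ExchangeFit",
    "compute_r2eff",
    "propagate_errors",
    "rex_test",
    "simulate_bloch_mcconnell",
    "fast_exchange_model",
    "slow_exchange_model",
    "fit_fast_exchange",
    "fit_slow_exchange",
    "analyze_dataset",
    "read_peak_table",
    "write_peak_table",
]

log = logging.getLogger(__name__)

DEFAULT_T_RLX = 0.040          # s, constant relaxation time
DEFAULT_MULTIPLIER = 1.65      # one-sided 95% significance on Rex


@dataclass
class DispersionDataset:
    """Raw peak amplitudes for one residue across the ν_CPMG series.

    ``replicates`` maps each ν (Hz) to the replicate amplitudes measured
    there; the reference amplitude (no CPMG element) is stored under ν = 0.
    """

    peak_id: str
    residue: int
    replicates: dict[float, np.ndarray]
    t_rlx: float = DEFAULT_T_RLX

    def __post_init__(self) -> None:
        if self.t_rlx <= 0:
            raise ConfigurationError("T_rlx must be positive")
        if 0.0 not in self.replicates:
            raise InputError(f"{self.peak_id}: missing reference (nu=0) row")
        self.replicates = {
            float(nu): np.atleast_1d(np.asarray(v, dtype=float))
            for nu, v in sorted(self.replicates.items())
        }

    @property
    def nu(self) -> np.ndarray:
        return np.array([n for n in self.replicates if n > 0.0])

    @property
    def i0(self) -> float:
        return float(np.mean(self.replicates[0.0]))

    def mean_intensity(self, nu: float) -> float:
        return float(np.mean(self.replicates[float(nu)]))


@dataclass
class DispersionProfile:
    """R2,eff(ν_CPMG) with standard errors."""

    peak_id: str
    residue: int
    nu: np.ndarray                 # Hz
    r2eff: np.ndarray              # s^-1
    sigma: np.ndarray              # s^-1

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.nu) == len(self.r2eff) == len(self.sigma)):
            raise InputError("profile arrays must have equal length")
        if np.any(self.sigma <= 0):
            raise InputError("profile errors must be positive")


@dataclass
class RexResult:
    rex: float
    sigma_rex: float
    multiplier: float
    significant: bool


@dataclass
class ExchangeFit:
    model: str                     # "fast" | "slow"
    r2_0: float                    # exchange-free rate, s^-1
    k_ex: float | None = None      # s^-1 (fast model)
    phi_ex: float | None = None    # rad^2 s^-2 (fast model)
    k_ab: float | None = None      # s^-1 (slow model)
    delta_omega: float | None = None  # rad s^-1 (slow model)
    p_b: float | None = None       # not identifiable in the fast regime
    errors: dict = field(default_factory=dict)
    chi2: float = math.nan
    chi2_reduced: float = math.nan
    aicc: float = math.nan
    n_points: int = 0


# ---------------------------------------------------------------------------
# R2,eff and errors

def compute_r2eff(i: float, i0: float, t_rlx: float = DEFAULT_T_RLX) -> float:
    """R2,eff = −ln(I/I₀)/T_rlx for a single amplitude pair."""
    if i0 <= 0 or t_rlx <= 0:
        raise InputError("I0 and T_rlx must be positive")
    if i <= 0:
        raise InputError("non-analyzable amplitude I <= 0")
    return -math.log(i / i0) / t_rlx


def propagate_errors(
    dataset: DispersionDataset,
    sigma_i: float | None = None,
    min_sigma_fraction: float = 0.01,
) -> DispersionProfile:
    """R2,eff profile with first-order propagated amplitude errors.

    The amplitude error σ_I is the pooled standard deviation over all ν
    points carrying replicates (the two-to-three replicate acquisition
    scheme); since each R2,eff is computed from the replicate-averaged
    amplitude, the propagated error is the standard error of that mean,
    σ_R2eff = σ_I/(√n_rep·I·T_rlx). Points with I ≤ 0, or exceeding I₀ by
    more than 3σ, are excluded and logged. Propagated errors are floored at
    ``min_sigma_fraction`` × |R2,eff| (and at an absolute 1e-6) to avoid
    zero-weight degeneracies.
    """
    if sigma_i is None:
        # pool over the replicated nu_CPMG points; the no-CPMG reference is
        # only used as a fallback (its amplitude scale differs)
        def pooled(include_ref: bool) -> tuple[float, int]:
            ss, dof = 0.0, 0
            for nu, v in dataset.replicates.items():
                if nu == 0.0 and not include_ref:
                    continue
                if len(v) >= 2:
                    ss += float(np.sum((v - v.mean()) ** 2))
                    dof += len(v) - 1
            return ss, dof

        ss, dof = pooled(include_ref=False)
        if dof == 0:
            ss, dof = pooled(include_ref=True)
        if dof == 0:
            raise ConfigurationError(
                f"{dataset.peak_id}: no replicated points; supply sigma_i"
            )
        sigma_i = math.sqrt(ss / dof)

    t = dataset.t_rlx
    i0 = dataset.i0
    nus, r2, sig = [], [], []
    for nu in dataset.nu:
        n_rep = len(dataset.replicates[float(nu)])
        i = dataset.mean_intensity(nu)
        if i <= 0:
            log.warning("%s: I(%g Hz) <= 0, excluded", dataset.peak_id, nu)
            continue
        if i > i0 + 3.0 * sigma_i:
            log.warning(
                "%s: I(%g Hz) exceeds I0 by > 3 sigma, excluded",
                dataset.peak_id, nu,
            )
            continue
        r = -math.log(i / i0) / t
        s = sigma_i / (math.sqrt(n_rep) * i * t)
        floor = max(min_sigma_fraction * abs(r), 1e-6)
        if s < floor:
            log.info("%s: sigma floored at %g Hz", dataset.peak_id, nu)
            s = floor
        nus.append(nu)
        r2.append(r)
        sig.append(s)
    return DispersionProfile(
        peak_id=dataset.peak_id,
        residue=dataset.residue,
        nu=np.array(nus),
        r2eff=np.array(r2),
        sigma=np.array(sig),
    )


def rex_test(
    profile: DispersionProfile, multiplier: float = DEFAULT_MULTIPLIER
) -> RexResult:
    """Exchange contribution Rex = R2,eff(ν_min) − R2,eff(ν_max).

    σ_Rex combines the two endpoint errors in quadrature; the profile is
    flagged when Rex > multiplier × σ_Rex (one-sided).
    """
    if len(profile.nu) < 2:
        raise InputError("need at least two nu points")
    i_min = int(np.argmin(profile.nu))
    i_max = int(np.argmax(profile.nu))
    rex = float(profile.r2eff[i_min] - profile.r2eff[i_max])
    sigma = float(math.hypot(profile.sigma[i_min], profile.sigma[i_max]))
    return RexResult(
        rex=rex,
        sigma_rex=sigma,
        multiplier=multiplier,
        significant=rex > multiplier * sigma,
    )


# ---------------------------------------------------------------------------
# Two-site Bloch-McConnell propagation

def _echo_counts(nu: float, t_rlx: float) -> int:
    """Number of τ-180°-τ blocks (each 1/(2ν) long) fitting in T_rlx."""
    n = max(int(round(2.0 * nu * t_rlx)), 1)
    if abs(n / (2.0 * nu) - t_rlx) > 1e-9:
        log.info(
            "nu=%g Hz: T_rlx not an integer number of echoes, using n=%d", nu, n
        )
    return n


def simulate_bloch_mcconnell(
    params: dict,
    nu_grid,
    t_rlx: float = DEFAULT_T_RLX,
    peak_id: str = "sim",
    residue: int = 0,
    sigma: float = 1e-6,
) -> DispersionProfile:
    """Numerical R2,eff(ν) for two-site in-phase exchange.

    The transverse magnetization (Mx, My) of both sites is propagated
    through the CPMG train: free evolution for τ = 1/(4ν), an ideal 180°
    pulse (My → −My), evolution for τ, repeated to fill ``t_rlx`` with the
    nearest realizable number of echoes. Parameters: ``k_ex`` (s⁻¹),
    ``p_b``, ``delta_omega`` (rad/s), ``r2a`` and ``r2b`` (s⁻¹).
    """
    from scipy.linalg import expm

    k_ex = float(params["k_ex"])
    p_b = float(params["p_b"])
    dw = float(params["delta_omega"])
    r2a = float(params["r2a"])
    r2b = float(params.get("r2b", r2a))
    if k_ex <= 0 or not (0.0 <= p_b < 1.0):
        raise InputError("need k_ex > 0 and 0 <= p_b < 1")
    p_a = 1.0 - p_b
    k_ab = k_ex * p_b
    k_ba = k_ex * p_a

    ll = np.array([
        [-r2a - k_ab, 0.0, k_ba, 0.0],
        [0.0, -r2a - k_ab, 0.0, k_ba],
        [k_ab, 0.0, -r2b - k_ba, -dw],
        [0.0, k_ab, dw, -r2b - k_ba],
    ])
    flip = np.diag([1.0, -1.0, 1.0, -1.0])
    m0 = np.array([p_a, 0.0, p_b, 0.0])

    nu_grid = np.asarray(nu_grid, dtype=float)
    r2eff = np.empty_like(nu_grid)
    for k, nu in enumerate(nu_grid):
        n_echo = _echo_counts(nu, t_rlx)
        tau = 1.0 / (4.0 * nu)
        u = expm(ll * tau)
        block = u @ flip @ u
        prop = np.linalg.matrix_power(block, n_echo)
        m = prop @ m0
        amp = m[0] + m[2]
        t_real = n_echo / (2.0 * nu)
        r2eff[k] = -math.log(max(amp, 1e-300)) / t_real
    return DispersionProfile(
        peak_id=peak_id,
        residue=residue,
        nu=nu_grid,
        r2eff=r2eff,
        sigma=np.full_like(nu_grid, sigma),
    )


# ---------------------------------------------------------------------------
# Analytic two-state models and fits

def fast_exchange_model(
    nu: np.ndarray, r2_0: float, phi_ex: float, k_ex: float
) -> np.ndarray:
    nu = np.asarray(nu, dtype=float)
    x = k_ex / (4.0 * nu)
    return r2_0 + (phi_ex / k_ex) * (1.0 - np.tanh(x) / x)


def slow_exchange_model(
    nu: np.ndarray, r2_0: float, k_ab: float, delta_omega: float
) -> np.ndarray:
    nu = np.asarray(nu, dtype=float)
    x = delta_omega / (4.0 * nu)
    return r2_0 + k_ab * (1.0 - np.sinc(x / math.pi))


_KEX_STARTS = (100.0, 300.0, 1000.0, 3000.0)


def _aicc(chi2: float, n: int, k: int) -> float:
    aic = chi2 + 2.0 * k
    if n - k - 1 > 0:
        return aic + 2.0 * k * (k + 1) / (n - k - 1)
    return math.inf


def _weighted_fit(profile, model_fn, param_defs, starts):
    """Multi-start weighted least squares via lmfit; best χ² wins."""
    import lmfit

    best = None
    for start in starts:
        pars = lmfit.Parameters()
        for name, (value, vmin, vmax) in {**param_defs, **start}.items():
            pars.add(name, value=value, min=vmin, max=vmax)

        def resid(p):
            vals = model_fn(profile.nu, **{n: p[n].value for n in p})
            return (vals - profile.r2eff) / profile.sigma

        try:
            res = lmfit.minimize(resid, pars, method="leastsq")
        except Exception:      # singular steps for hopeless starts
            continue
        if best is None or res.chisqr < best.chisqr - 1e-12:
            best = res
    if best is None or not best.success:
        raise FitError(
            f"{profile.peak_id}: exchange fit did not converge"
            + (f" (best chi2 {best.chisqr:.3g})" if best else "")
        )
    return best


def fit_fast_exchange(profile: DispersionProfile) -> ExchangeFit:
    """Fit the fast-exchange closed form (R2°, Φ_ex, k_ex)."""
    if len(profile.nu) < 4:
        raise InputError("need at least 4 nu points")
    rex_guess = max(float(profile.r2eff.max() - profile.r2eff.min()), 0.1)
    defs = {
        "r2_0": (float(profile.r2eff.min()), 0.0, None),
        "phi_ex": (rex_guess * 1000.0, 1e-6, None),
        "k_ex": (1000.0, 1.0, 1e6),
    }
    starts = [
        {"k_ex": (k0, 1.0, 1e6), "phi_ex": (rex_guess * k0, 1e-6, None)}
        for k0 in _KEX_STARTS
    ]
    res = _weighted_fit(profile, fast_exchange_model, defs, starts)
    n = len(profile.nu)
    err = {
        name: (float(res.params[name].stderr) if res.params[name].stderr else math.nan)
        for name in res.params
    }
    return ExchangeFit(
        model="fast",
        r2_0=float(res.params["r2_0"].value),
        phi_ex=float(res.params["phi_ex"].value),
        k_ex=float(res.params["k_ex"].value),
        p_b=None,                    # unidentifiable in the fast regime
        errors=err,
        chi2=float(res.chisqr),
        chi2_reduced=float(res.chisqr / max(n - 3, 1)),
        aicc=_aicc(float(res.chisqr), n, 3),
        n_points=n,
    )


def fit_slow_exchange(profile: DispersionProfile) -> ExchangeFit:
    """Fit the slow-exchange closed form (R2°, k_ab, Δω)."""
    if len(profile.nu) < 4:
        raise InputError("need at least 4 nu points")
    rex_guess = max(float(profile.r2eff.max() - profile.r2eff.min()), 0.1)
    defs = {
        "r2_0": (float(profile.r2eff.min()), 0.0, None),
        "k_ab": (rex_guess, 1e-6, None),
        "delta_omega": (1000.0, 1.0, 1e6),
    }
    starts = [{"delta_omega": (w0, 1.0, 1e6)} for w0 in (200.0, 800.0, 2000.0, 6000.0)]
    res = _weighted_fit(profile, slow_exchange_model, defs, starts)
    n = len(profile.nu)
    err = {
        name: (float(res.params[name].stderr) if res.params[name].stderr else math.nan)
        for name in res.params
    }
    return ExchangeFit(
        model="slow",
        r2_0=float(res.params["r2_0"].value),
        k_ab=float(res.params["k_ab"].value),
        delta_omega=float(res.params["delta_omega"].value),
        errors=err,
        chi2=float(res.chisqr),
        chi2_reduced=float(res.chisqr / max(n - 3, 1)),
        aicc=_aicc(float(res.chisqr), n, 3),
        n_points=n,
    )


def analyze_dataset(
    datasets,
    multiplier: float = DEFAULT_MULTIPLIER,
    model: str = "auto",
    sigma_i: float | None = None,
):
    """Per-residue dispersion analysis table.

    Each dataset is converted to an R2,eff profile; only residues whose Rex
    passes the significance threshold are fitted. With ``model="auto"`` the
    fast and slow closed forms are both fitted and the small-sample
    corrected Akaike criterion picks the winner.

    Returns a pandas DataFrame sorted by Rex (descending).
    """
    import pandas as pd

    rows = []
    for ds in datasets:
        profile = propagate_errors(ds, sigma_i=sigma_i)
        rt = rex_test(profile, multiplier)
        row = {
            "peak_id": ds.peak_id,
            "residue": ds.residue,
            "rex": rt.rex,
            "sigma_rex": rt.sigma_rex,
            "significant": rt.significant,
            "model": None,
            "k_ex": np.nan,
            "phi_ex": np.nan,
            "k_ab": np.nan,
            "delta_omega": np.nan,
            "r2_0": np.nan,
            "chi2_reduced": np.nan,
        }
        if rt.significant and len(profile.nu) >= 4:
            fits = []
            for name, fn in (("fast", fit_fast_exchange), ("slow", fit_slow_exchange)):
                if model in ("auto", name):
                    try:
                        fits.append(fn(profile))
                    except FitError:
                        log.warning("%s: %s fit failed", ds.peak_id, name)
            if fits:
                best = min(fits, key=lambda f: f.aicc)
                row.update(
                    model=best.model,
                    r2_0=best.r2_0,
                    chi2_reduced=best.chi2_reduced,
                )
                if best.model == "fast":
                    row.update(k_ex=best.k_ex, phi_ex=best.phi_ex)
                else:
                    row.update(k_ab=best.k_ab, delta_omega=best.delta_omega)
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values("rex", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# TSV dialect: peak_id, residue, nu_cpmg_hz, intensity, replicate_id

def read_peak_table(path: str | Path, t_rlx: float = DEFAULT_T_RLX):
    """Read CPMG peak amplitudes (reference rows have nu_cpmg_hz = 0)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"peak_id", "residue", "nu_cpmg_hz", "intensity"}
    if not required.issubset(df.columns):
        raise InputError(f"peak table needs columns {sorted(required)}")
    datasets = []
    for pid, grp in df.groupby("peak_id", sort=True):
        reps = {
            float(nu): sub["intensity"].to_numpy()
            for nu, sub in grp.groupby("nu_cpmg_hz")
        }
        datasets.append(
            DispersionDataset(
                peak_id=str(pid),
                residue=int(grp["residue"].iloc[0]),
                replicates=reps,
                t_rlx=t_rlx,
            )
        )
    return datasets


def write_peak_table(datasets, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for ds in datasets:
        for nu, vals in ds.replicates.items():
            for rep, v in enumerate(vals):
                rows.append(
                    {
                        "peak_id": ds.peak_id,
                        "residue": ds.residue,
                        "nu_cpmg_hz": nu,
                        "intensity": v,
                        "replicate_id": rep,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
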