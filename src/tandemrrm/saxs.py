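"""Guinier analysis of 1D SAXS profiles and pressure-resolved Rg tables.

In the low-q (Guinier) regime a globular scatterer obeys
ln I(q) = ln I₀ − Rg²q²/3, valid roughly for q·Rg ≤ 1.3. ``guinier_fit``
performs the weighted linear regression of ln I on q² over a fixed window;
``auto_guinier`` grows the window from low q until the q·Rg limit is
violated, iterating to self-consistency. ``rg_vs_pressure`` assembles
per-variant Rg(p) tables and flags discontinuous jumps as unfolding /
expansion candidates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, InputError

__all__ = [
    "SAXSProfile",
    "GuinierFit",
    "read_profile",
    "write_profile",
    "guinier_fit",
    "auto_guinier",
    "rg_vs_pressure",
    "sphere_form_factor",
    "sphere_rg",
]

log = logging.getLogger(__name__)

DEFAULT_QRG_LIMIT = 1.3


@dataclass
class SAXSProfile:
    """A 1D scattering profile (q in Å⁻¹, I in arbitrary units)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    label: str = ""
    pressure_bar: float = math.nan
    sigma_is_default: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise FormatError("q must be strictly increasing")
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise InputError("profile columns must have equal length")


@dataclass
class GuinierFit:
    rg: float                     # Å
    rg_err: float
    i0: float
    i0_err: float
    q_window: tuple[float, float]
    n_points: int
    qrg_min: float
    qrg_max: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))


def read_profile(path: str | Path, label: str = "",
                 pressure_bar: float = math.nan) -> SAXSProfile:
    """Read a 2- or 3-column ASCII profile; '#' lines are comments.

    Without a third column the error defaults to √I (flagged on the
    returned profile and logged).
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if data.shape[1] not in (2, 3):
        raise FormatError(f"{path}: expected 2 or 3 columns, got {data.shape[1]}")
    q, i = data[:, 0], data[:, 1]
    default_sigma = data.shape[1] == 2
    if default_sigma:
        log.warning("%s: no error column, using sqrt(I)", path)
        sigma = np.sqrt(np.clip(i, 0.0, None))
    else:
        sigma = data[:, 2]
    return SAXSProfile(
        q=q, intensity=i, sigma=sigma, label=label or path.stem,
        pressure_bar=pressure_bar, sigma_is_default=default_sigma,
    )


def write_profile(profile: SAXSProfile, path: str | Path) -> None:
    header = f"q(1/A) I(a.u.) sigma  [{profile.label}]"
    np.savetxt(
        path,
        np.column_stack([profile.q, profile.intensity, profile.sigma]),
        header=header,
    )


def guinier_fit(
    profile: SAXSProfile, q_window: tuple[float, float] | None = None
) -> GuinierFit:
    """Weighted linear regression of ln I on q² over the given window.

    Rg = √(−3·slope); parameter errors come from the regression covariance
    with σ_lnI = σ/I. Points with I ≤ 0 are excluded.
    """
    q, i, s = profile.q, profile.intensity, profile.sigma
    mask = i > 0
    if q_window is not None:
        mask &= (q >= q_window[0]) & (q <= q_window[1])
    if mask.sum() < 5:
        raise InputError("need at least 5 positive-intensity points in window")
    q, i, s = q[mask], i[mask], s[mask]

    x = q**2
    y = np.log(i)
    w = np.where(np.isfinite(s) & (s > 0), (i / s) ** 2, 1.0)  # 1/σ_lnI²
    # weighted least squares, 2 parameters
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    inter = ym - slope * xm
    if slope >= 0:
        raise InputError("no Guinier decay: non-negative slope")
    resid = y - (inter + slope * x)
    n = len(x)
    chi2 = float((w * resid**2).sum())
    scale = chi2 / max(n - 2, 1) if n > 2 else 1.0
    var_slope = scale / sxx
    var_inter = scale * (1.0 / sw + xm**2 / sxx)

    rg = math.sqrt(-3.0 * slope)
    # Rg = √(−3·slope) ⇒ dRg/dslope = −3/(2Rg)
    rg_err = 1.5 * math.sqrt(var_slope) / rg if rg > 0 else math.nan
    return GuinierFit(
        rg=rg,
        rg_err=rg_err,
        i0=math.exp(inter),
        i0_err=math.exp(inter) * math.sqrt(var_inter),
        q_window=(float(q[0]), float(q[-1])),
        n_points=n,
        qrg_min=float(q[0] * rg),
        qrg_max=float(q[-1] * rg),
        residuals=resid,
    )


def auto_guinier(
    profile: SAXSProfile,
    qrg_limit: float = DEFAULT_QRG_LIMIT,
    min_points: int = 5,
    max_iterations: int = 50,
    trim_low_q: bool = False,
) -> GuinierFit:
    """Self-consistent Guinier window from low q up to q·Rg ≤ limit.

    Starting from an initial low-q fit, the window's upper edge is moved to
    limit/Rg and the fit repeated until the window stabilizes. With
    ``trim_low_q`` the first points are dropped while doing so improves the
    reduced residual scatter (beamstop-artifact guard).
    """
    q = profile.q
    start = 0
    fit = None
    for start_try in range(0, 4 if trim_low_q else 1):
        lo = start_try
        hi = max(min_points + lo, min(len(q), 10 + lo))
        window = (float(q[lo]), float(q[hi - 1]))
        prev_hi = -1
        try:
            for _ in range(max_iterations):
                f = guinier_fit(profile, window)
                new_hi = float(qrg_limit / f.rg)
                n_in = int(np.sum((q >= window[0]) & (q <= new_hi) & (profile.intensity > 0)))
                if n_in < min_points:
                    raise InputError("window collapsed below minimum size")
                if abs(new_hi - window[1]) < 1e-12 or n_in == prev_hi:
                    window = (window[0], new_hi)
                    break
                prev_hi = n_in
                window = (window[0], new_hi)
            cand = guinier_fit(profile, window)
        except InputError:
            continue
        score = float(np.mean(cand.residuals**2))
        if fit is None or score < best_score * 0.5:
            fit, best_score = cand, score
    if fit is None:
        raise InputError("no self-consistent Guinier window found")
    if fit.qrg_max > qrg_limit * 1.001:
        raise InputError("window violates its own q·Rg limit")
    return fit


def rg_vs_pressure(profiles, qrg_limit: float = DEFAULT_QRG_LIMIT,
                   jump_sigma: float = 3.0):
    """Rg(p) table per variant with discontinuity flags.

    Adjacent pressures whose Rg differ by more than ``jump_sigma`` joint
    standard errors are flagged as transition candidates.
    """
    import pandas as pd

    rows = []
    for prof in profiles:
        f = auto_guinier(prof, qrg_limit=qrg_limit)
        rows.append(
            {
                "label": prof.label,
                "pressure_bar": prof.pressure_bar,
                "rg_A": f.rg,
                "rg_err_A": f.rg_err,
                "qrg_max": f.qrg_max,
                "jump": False,
            }
        )
    df = pd.DataFrame(rows).sort_values(["label", "pressure_bar"]).reset_index(drop=True)
    for label, grp in df.groupby("label"):
        idx = grp.index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            joint = math.hypot(df.loc[a, "rg_err_A"], df.loc[b, "rg_err_A"])
            if joint > 0 and abs(df.loc[b, "rg_A"] - df.loc[a, "rg_A"]) > jump_sigma * joint:
                df.loc[b, "jump"] = True
    return df


# ---------------------------------------------------------------------------
# Reference form factors

def sphere_form_factor(q, radius: float, i0: float = 1.0):
    """Scattering intensity of a homogeneous sphere of the given radius."""
    q = np.asarray(q, dtype=float)
    x = q * radius
    with np.errstate(divide="ignore", invalid="ignore"):
        f = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    f = np.where(x == 0, 1.0, f)
    return i0 * f**2


def sphere_rg(radius: float) -> float:
    """Rg of a homogeneous sphere: √(3/5)·R."""
    return math.sqrt(3.0 / 5.0) * radius
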