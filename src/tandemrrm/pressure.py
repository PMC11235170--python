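"""Pressure-induced unfolding analysis of per-peak NMR crosspeak intensities.

Native crosspeak intensity is modelled as proportional to the folded
population of a two-state unfolder whose free energy is linear in pressure:

    ΔG_u(p) = ΔG_u0 + ΔV_u · (p − p0)
    f_folded(p) = 1 / (1 + exp(−ΔG_u(p)/RT))
    I_native(p) = A · f_folded(p),  I_unfolded(p) = B · (1 − f_folded(p))

with ΔG_u0 in kJ/mol at the reference pressure p0, ΔV_u in mL/mol
(negative when pressure destabilizes the fold), and the unfolding midpoint
p_1/2 = p0 − ΔG_u0/ΔV_u where ΔG_u vanishes. The module also provides the
per-peak attenuation statistic a = 1 − I(2.5 kbar)/I(1 bar) and the
sensitive/resistant classification of peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, FitError, InputError, NormalizationError

__all__ = [
    "PressureSeries",
    "TwoStateFit",
    "AttenuationTable",
    "PAPER_GRID_BAR",
    "normalize_series",
    "attenuation",
    "attenuation_table",
    "two_state_intensity",
    "folded_fraction",
    "midpoint_pressure",
    "fit_two_state",
    "classify_peaks",
    "mean_profile",
    "read_pressure_table",
    "write_pressure_table",
]

log = logging.getLogger(__name__)

R_GAS = 8.314                 # J/(mol K)
ML_BAR_TO_J = 0.1             # 1 mL/mol · 1 bar = 0.1 J/mol
DEFAULT_TEMPERATURE = 290.0   # K, acquisition temperature
DEFAULT_P0 = 1.0              # bar
# acquisition grid: 1 bar, then every 250 bar up to 2.5 kbar
PAPER_GRID_BAR = np.concatenate([[1.0], np.arange(250.0, 2501.0, 250.0)])


@dataclass
class PressureSeries:
    """Intensity versus pressure for one crosspeak."""

    peak_id: str
    pressure: np.ndarray          # bar, strictly increasing
    intensity: np.ndarray         # arbitrary units, >= 0 (NaN = missing)
    sigma: np.ndarray | None = None
    species: str = "native"       # "native" | "unfolded"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.pressure) <= 0):
            raise InputError(f"{self.peak_id}: pressures must be strictly increasing")
        if len(self.pressure) != len(self.intensity):
            raise InputError("pressure and intensity lengths differ")
        if np.any(self.intensity[np.isfinite(self.intensity)] < 0):
            raise InputError("intensities must be non-negative")
        if self.species not in ("native", "unfolded"):
            raise InputError(f"unknown species {self.species!r}")
        if self.sigma is None:
            self.sigma = np.full_like(self.intensity, np.nan)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)

    def intensity_at(self, p: float) -> float:
        """Intensity at the grid point nearest to pressure p (bar)."""
        return float(self.intensity[int(np.argmin(np.abs(self.pressure - p)))])


@dataclass
class TwoStateFit:
    dg0_kj_mol: float                   # unfolding free energy at p0
    dv_ml_mol: float                    # unfolding volume change
    amplitude_native: float | None
    amplitude_unfolded: float | None
    p_half_bar: float
    p0_bar: float
    temperature: float
    errors: dict = field(default_factory=dict)
    chi2: float = math.nan
    chi2_reduced: float = math.nan
    flags: list[str] = field(default_factory=list)


@dataclass
class AttenuationTable:
    """Per-peak percent attenuation between 1 bar and 2.5 kbar."""

    peak_ids: list[str]
    attenuation_pct: np.ndarray
    labels: list[str] | None = None     # sensitive / resistant
    bimodality_gap: float = math.nan

    @property
    def mean(self) -> float:
        return float(np.mean(self.attenuation_pct))

    @property
    def median(self) -> float:
        return float(np.median(self.attenuation_pct))

    def histogram(self, bins=20, range_=(-20.0, 100.0)):
        return np.histogram(self.attenuation_pct, bins=bins, range=range_)

    def to_frame(self):
        import pandas as pd

        data = {"peak_id": self.peak_ids, "attenuation_pct": self.attenuation_pct}
        if self.labels is not None:
            data["label"] = self.labels
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Elementary operations

def normalize_series(series: PressureSeries) -> PressureSeries:
    """Divide a series by its lowest-pressure intensity (idempotent)."""
    ref = series.intensity[0]
    if not np.isfinite(ref) or ref <= 0:
        raise NormalizationError(
            f"{series.peak_id}: zero or missing reference intensity"
        )
    return PressureSeries(
        peak_id=series.peak_id,
        pressure=series.pressure.copy(),
        intensity=series.intensity / ref,
        sigma=series.sigma / ref,
        species=series.species,
        temperature=series.temperature,
    )


def attenuation(
    series: PressureSeries, p_low: float = 1.0, p_high: float = 2500.0
) -> float:
    """Percent attenuation a = 100·[1 − I(p_high)/I(p_low)] (may be < 0)."""
    span = series.pressure.max() - series.pressure.min()
    if (
        abs(series.pressure.min() - p_low) > 0.1 * span
        or abs(series.pressure.max() - p_high) > 0.1 * span
    ):
        raise InputError(
            f"{series.peak_id}: series does not span {p_low}-{p_high} bar"
        )
    i_low = series.intensity_at(p_low)
    i_high = series.intensity_at(p_high)
    if not (np.isfinite(i_low) and np.isfinite(i_high)) or i_low <= 0:
        raise InputError(f"{series.peak_id}: endpoint intensity missing")
    return 100.0 * (1.0 - i_high / i_low)


def attenuation_table(
    collection, p_low: float = 1.0, p_high: float = 2500.0
) -> AttenuationTable:
    ids, vals = [], []
    for s in collection:
        try:
            vals.append(attenuation(s, p_low, p_high))
            ids.append(s.peak_id)
        except InputError as exc:
            log.warning("skipping %s: %s", s.peak_id, exc)
    if not ids:
        raise InputError("no series span the requested pressure endpoints")
    return AttenuationTable(peak_ids=ids, attenuation_pct=np.array(vals))


# ---------------------------------------------------------------------------
# Two-state thermodynamics

def folded_fraction(
    p, dg0_kj_mol: float, dv_ml_mol: float,
    temperature: float = DEFAULT_TEMPERATURE, p0: float = DEFAULT_P0,
    dbeta_ml_mol_bar: float = 0.0,
):
    """Folded population under the (linear by default) two-state model.

    ``dbeta_ml_mol_bar`` adds the optional second-order compressibility
    term −(Δβ_u/2)(p − p0)²; it is zero in the default linear model.
    """
    p = np.asarray(p, dtype=float)
    dp = p - p0
    dg = (
        1000.0 * dg0_kj_mol
        + dv_ml_mol * ML_BAR_TO_J * dp
        - 0.5 * dbeta_ml_mol_bar * ML_BAR_TO_J * dp**2
    )  # J/mol
    return 1.0 / (1.0 + np.exp(-dg / (R_GAS * temperature)))


def two_state_intensity(
    p, amplitude: float, dg0_kj_mol: float, dv_ml_mol: float,
    temperature: float = DEFAULT_TEMPERATURE, p0: float = DEFAULT_P0,
    species: str = "native",
):
    f = folded_fraction(p, dg0_kj_mol, dv_ml_mol, temperature, p0)
    return amplitude * (f if species == "native" else 1.0 - f)


def midpoint_pressure(
    dg0_kj_mol: float, dv_ml_mol: float, p0: float = DEFAULT_P0
) -> float:
    """p_1/2 = p0 − ΔG_u0/ΔV_u (bar); requires ΔV_u ≠ 0."""
    if dv_ml_mol == 0:
        raise InputError("ΔV_u = 0 has no unfolding midpoint")
    return p0 - 1000.0 * dg0_kj_mol / (dv_ml_mol * ML_BAR_TO_J)


def fit_two_state(
    native: PressureSeries,
    unfolded: PressureSeries | None = None,
    temperature: float | None = None,
    p0: float = DEFAULT_P0,
    min_attenuation_pct: float = 20.0,
    fit_compressibility: bool = False,
) -> TwoStateFit:
    """Weighted two-state fit of intensity versus pressure.

    Fits (ΔG_u0, ΔV_u, amplitudes) to a native series, jointly with a paired
    unfolded-species series when supplied (total population conserved by
    construction). Series showing less than ``min_attenuation_pct`` decay
    are flagged "insufficient transition" and not fitted; a fitted
    ΔV_u ≥ 0 raises a sign warning flag (unfolding not pressure-favored).
    The midpoint error follows from the parameter covariance by first-order
    propagation.
    """
    import lmfit

    t_kelvin = temperature or native.temperature
    if len(native.pressure) < 5:
        raise InputError("need at least 5 pressure points")
    flags: list[str] = []
    att = 100.0 * (1.0 - native.intensity[-1] / native.intensity[0])
    if att < min_attenuation_pct:
        return TwoStateFit(
            dg0_kj_mol=math.nan, dv_ml_mol=math.nan,
            amplitude_native=None, amplitude_unfolded=None,
            p_half_bar=math.nan, p0_bar=p0, temperature=t_kelvin,
            flags=["insufficient transition"],
        )

    def weights(series):
        s = series.sigma
        if s is None or np.all(~np.isfinite(s)):
            return np.full_like(series.intensity, 0.02 * series.intensity[0])
        return np.where(np.isfinite(s) & (s > 0), s, np.nanmedian(s))

    pars = lmfit.Parameters()
    pars.add("dg0", value=5.0, min=-50.0, max=200.0)       # kJ/mol
    pars.add("dv", value=-50.0, min=-500.0, max=500.0)     # mL/mol
    pars.add("dbeta", value=0.0, vary=fit_compressibility)  # mL/(mol bar)
    pars.add("amp_n", value=float(native.intensity[0]), min=1e-12)
    if unfolded is not None:
        pars.add("amp_u", value=float(np.nanmax(unfolded.intensity) or 1.0), min=1e-12)

    wn = weights(native)
    mask_n = np.isfinite(native.intensity)
    if unfolded is not None:
        wu = weights(unfolded)
        mask_u = np.isfinite(unfolded.intensity)

    def resid(p):
        f_n = folded_fraction(native.pressure, p["dg0"].value, p["dv"].value,
                              t_kelvin, p0, p["dbeta"].value)
        out = [(p["amp_n"].value * f_n - native.intensity)[mask_n] / wn[mask_n]]
        if unfolded is not None:
            f_u = folded_fraction(unfolded.pressure, p["dg0"].value,
                                  p["dv"].value, t_kelvin, p0,
                                  p["dbeta"].value)
            out.append(
                (p["amp_u"].value * (1.0 - f_u) - unfolded.intensity)[mask_u]
                / wu[mask_u]
            )
        return np.concatenate(out)

    res = lmfit.minimize(resid, pars, method="leastsq")
    if not res.success:
        raise FitError(f"{native.peak_id}: two-state fit did not converge")
    dg0 = float(res.params["dg0"].value)
    dv = float(res.params["dv"].value)
    if dv >= 0:
        flags.append("ΔV_u >= 0: unfolding not pressure-favored")
        log.warning("%s: fitted ΔV_u >= 0", native.peak_id)
    p_half = midpoint_pressure(dg0, dv, p0) if dv != 0 else math.nan

    errors: dict[str, float] = {}
    for name in res.params:
        se = res.params[name].stderr
        errors[name] = float(se) if se else math.nan
    # d(p_half)/d(dg0) = -1000/(0.1 dv); d(p_half)/d(dv) = 1000 dg0/(0.1 dv^2)
    if res.covar is not None and dv != 0:
        names = [n for n in res.params if res.params[n].vary]
        gvec = np.zeros(len(names))
        if "dg0" in names:
            gvec[names.index("dg0")] = -1000.0 / (ML_BAR_TO_J * dv)
        if "dv" in names:
            gvec[names.index("dv")] = 1000.0 * dg0 / (ML_BAR_TO_J * dv**2)
        errors["p_half"] = float(np.sqrt(gvec @ res.covar @ gvec))

    n_obs = int(mask_n.sum()) + (int(mask_u.sum()) if unfolded is not None else 0)
    return TwoStateFit(
        dg0_kj_mol=dg0,
        dv_ml_mol=dv,
        amplitude_native=float(res.params["amp_n"].value),
        amplitude_unfolded=(
            float(res.params["amp_u"].value) if unfolded is not None else None
        ),
        p_half_bar=p_half,
        p0_bar=p0,
        temperature=t_kelvin,
        errors=errors,
        chi2=float(res.chisqr),
        chi2_reduced=float(res.chisqr / max(n_obs - res.nvarys, 1)),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Cohort statistics

def classify_peaks(
    table: AttenuationTable, threshold_pct: float = 50.0
) -> AttenuationTable:
    """Label peaks sensitive (≥ threshold) or resistant (< threshold).

    The bimodality gap is the difference between group means divided by the
    pooled within-group standard deviation (NaN when a group is empty).
    """
    if len(table.peak_ids) == 0:
        raise InputError("empty attenuation table")
    a = table.attenuation_pct
    labels = ["sensitive" if v >= threshold_pct else "resistant" for v in a]
    sens = a[a >= threshold_pct]
    resi = a[a < threshold_pct]
    if len(sens) and len(resi):
        dof = max(len(sens) + len(resi) - 2, 1)
        pooled = math.sqrt(
            (np.sum((sens - sens.mean()) ** 2) + np.sum((resi - resi.mean()) ** 2))
            / dof
        )
        gap = (sens.mean() - resi.mean()) / pooled if pooled > 0 else math.inf
    else:
        gap = math.nan
    return AttenuationTable(
        peak_ids=list(table.peak_ids),
        attenuation_pct=a.copy(),
        labels=labels,
        bimodality_gap=float(gap),
    )


def mean_profile(collection) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation of normalized series.

    Series on different grids are linearly interpolated onto the union grid.
    Returns (pressure grid, mean, sd).
    """
    series = [normalize_series(s) for s in collection]
    grid = np.unique(np.concatenate([s.pressure for s in series]))
    stack = np.vstack(
        [np.interp(grid, s.pressure, s.intensity) for s in series]
    )
    return grid, stack.mean(axis=0), stack.std(axis=0)


# ---------------------------------------------------------------------------
# TSV dialect: peak_id, species, pressure_bar, intensity, sigma

def read_pressure_table(
    path: str | Path, temperature: float = DEFAULT_TEMPERATURE
) -> list[PressureSeries]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"peak_id", "species", "pressure_bar", "intensity"}
    if not required.issubset(df.columns):
        raise InputError(f"pressure table needs columns {sorted(required)}")
    out = []
    for (pid, species), grp in df.groupby(["peak_id", "species"], sort=True):
        grp = grp.sort_values("pressure_bar")
        out.append(
            PressureSeries(
                peak_id=str(pid),
                pressure=grp["pressure_bar"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
                sigma=(
                    grp["sigma"].to_numpy() if "sigma" in grp.columns else None
                ),
                species=str(species),
                temperature=temperature,
            )
        )
    return out


def write_pressure_table(collection, path: str | Path) -> None:
    import pandas as pd

    rows = []
    for s in collection:
        for p, i, sg in zip(s.pressure, s.intensity, s.sigma):
            rows.append(
                {
                    "peak_id": s.peak_id,
                    "species": s.species,
                    "pressure_bar": p,
                    "intensity": i,
                    "sigma": sg,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
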