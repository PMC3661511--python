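"""Whole-cell saturation-binding analysis.

Specific binding is total minus nonspecific counts, normalized to protein.
Two summary fits are supported: the one-site hyperbola b = Bmax*l/(Kd+l)
(receptor density and affinity) and the variable-slope sigmoid on log10
concentration (Hill slope; 1 for a single independent site, up to 2 for two
cooperatively linked sites on a dimer).  Both are unweighted nonlinear least
squares, matching the conventional Prism-style analysis of such data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .units import (  # re-exported: unit conversions are part of this surface
    ConversionConstants,
    cpm_to_fmol_per_mg,
    gr_per_cell,
    transfection_correction,
)

log = logging.getLogger(__name__)

SATURATION_COLUMNS = [
    "l_hot_nM",
    "total_cpm",
    "nonspecific_cpm",
    "protein_mg",
    "replicate",
    "condition",
]


@dataclass(frozen=True)
class BindingFit:
    """One-site hyperbola fit: affinity Kd (nM) and capacity Bmax."""

    kd: float
    bmax: float
    kd_se: float
    bmax_se: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.bmax <= 0:
            raise ValueError("kd and bmax must be positive")

    def predict(self, l: np.ndarray) -> np.ndarray:
        l = np.asarray(l, dtype=float)
        return self.bmax * l / (self.kd + l)


@dataclass(frozen=True)
class HillFit:
    """Variable-slope sigmoid fit on log10 concentration, bottom fixed at 0."""

    hill_slope: float
    log_khalf: float  # log10 nM
    top: float
    hill_slope_se: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be positive")

    @property
    def hill_slope_ci95(self) -> tuple[float, float]:
        half = 1.96 * self.hill_slope_se
        return (self.hill_slope - half, self.hill_slope + half)

    def predict(self, log_l: np.ndarray) -> np.ndarray:
        log_l = np.asarray(log_l, dtype=float)
        return self.top / (1.0 + 10.0 ** ((self.log_khalf - log_l) * self.hill_slope))


def validate_saturation_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SATURATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"saturation table missing columns: {missing}")
    if (df["l_hot_nM"] < 0).any() or (df[["total_cpm", "nonspecific_cpm"]] < 0).any().any():
        raise ValueError("concentrations and counts must be non-negative")
    if (df["protein_mg"] <= 0).any():
        raise ValueError("protein_mg must be positive")
    if df["l_hot_nM"].nunique() < 4:
        raise ValueError("need >= 4 distinct hot-ligand concentrations")
    return df


def specific_binding(dataset: pd.DataFrame) -> pd.DataFrame:
    """Per-record specific binding in cpm/mg protein.

    Each record carries matched total and nonspecific counts at the same
    hot-ligand concentration and replicate.  Where assay noise pushes
    nonspecific above total, specific binding is clipped at zero with a
    logged warning.
    """
    df = validate_saturation_table(dataset)
    if df[["total_cpm", "nonspecific_cpm"]].isna().any().any():
        bad = df.loc[
            df[["total_cpm", "nonspecific_cpm"]].isna().any(axis=1), "l_hot_nM"
        ].tolist()
        raise ValueError(f"unmatched total/nonspecific records at l_hot_nM={bad}")
    raw = df["total_cpm"] - df["nonspecific_cpm"]
    n_neg = int((raw < 0).sum())
    if n_neg:
        log.warning("clipped %d negative specific-binding values to 0", n_neg)
    out = df.copy()
    out["specific_cpm_per_mg"] = raw.clip(lower=0) / df["protein_mg"]
    return out


def fit_one_site(l_nm, specific) -> BindingFit:
    """Fit the one-site binding hyperbola b = Bmax*l/(Kd+l)."""
    l = np.asarray(l_nm, dtype=float)
    b = np.asarray(specific, dtype=float)
    if l.size < 4:
        raise ValueError("need at least 4 points to fit")
    if not np.any(b > 0):
        raise ValueError("all-zero binding data; nothing to fit")
    if np.ptp(b) < 1e-12 * abs(b.max()):
        raise ValueError("flat binding data; hyperbola is unidentifiable")
    scale = float(b.max())  # fit on O(1) values so tolerances are relative
    bs = b / scale
    pos = l[l > 0]
    kd0 = float(np.median(pos)) if pos.size else 1.0
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, bmax, kd: bmax * x / (kd + x),
            l,
            bs,
            p0=[1.2, kd0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - depends on data
        raise ValueError(f"one-site fit did not converge: {err}") from err
    bmax, kd = popt[0] * scale, popt[1]
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    se[0] *= scale
    resid = b - bmax * l / (kd + l)
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return BindingFit(kd=float(kd), bmax=float(bmax), kd_se=float(se[1]),
                      bmax_se=float(se[0]), r_squared=r2)


def fit_hill(log10_l_nm, specific) -> HillFit:
    """Fit b = top / (1 + 10^((logK - log l) * n)) on log10 concentration.

    Bottom is fixed at 0 (binding starts from zero); top and the half-maximal
    point are free.  Points must span at least two decades.
    """
    x = np.asarray(log10_l_nm, dtype=float)
    b = np.asarray(specific, dtype=float)
    finite = np.isfinite(x)
    x, b = x[finite], b[finite]
    if x.size < 5:
        raise ValueError("need at least 5 finite points to fit")
    if np.ptp(x) < 2.0:
        raise ValueError("concentrations must span >= 2 decades")
    if not np.any(b > 0) or np.ptp(b) < 1e-12 * abs(b.max()):
        raise ValueError("flat or all-zero data; sigmoid is unidentifiable")
    scale = float(b.max())
    bs = b / scale
    k0 = float(x[np.argmin(np.abs(bs - 0.5))])
    try:
        popt, pcov = optimize.curve_fit(
            lambda lx, top, logk, n: top / (1.0 + 10.0 ** ((logk - lx) * n)),
            x,
            bs,
            p0=[1.0, k0, 1.0],
            bounds=([1e-12, x.min() - 6, 0.05], [np.inf, x.max() + 6, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover
        raise ValueError(f"Hill fit did not converge: {err}") from err
    top, logk, n = popt[0] * scale, popt[1], popt[2]
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    pred = top / (1.0 + 10.0 ** ((logk - x) * n))
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    r2 = 1.0 - float(np.sum((b - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return HillFit(hill_slope=float(n), log_khalf=float(logk), top=float(top),
                   hill_slope_se=float(se[2]), r_squared=r2)


def fit_saturation(dataset: pd.DataFrame) -> tuple[BindingFit, HillFit]:
    """Specific binding -> both summary fits, averaging replicates per dose."""
    spec = specific_binding(dataset)
    mean = spec.groupby("l_hot_nM", as_index=False)["specific_cpm_per_mg"].mean()
    mean = mean[mean["l_hot_nM"] > 0]
    one = fit_one_site(mean["l_hot_nM"], mean["specific_cpm_per_mg"])
    hill = fit_hill(np.log10(mean["l_hot_nM"]), mean["specific_cpm_per_mg"])
    return one, hill


def occupancy_span_ratio(n1: float, n2: float) -> float:
    """Fold-change in the ligand span covering 10% -> 90% occupancy.

    For a Hill curve with coefficient n, occupancy 0.9 needs (l/K)^n = 9 and
    occupancy 0.1 needs (l/K)^n = 1/9, so the 10-90% span is 81^(1/n).
    Returns span(n1)/span(n2): > 1 when n2 is the steeper (more cooperative)
    curve, i.e. the fold-decrease in ligand range needed to switch the
    receptor from mostly empty to mostly occupied.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("Hill coefficients must be positive")
    return 81.0 ** (1.0 / n1) / 81.0 ** (1.0 / n2)


@dataclass(frozen=True)
class ImmunoblotCalibration:
    """Linear pixels -> cpm/mg calibration with its fit quality."""

    slope: float
    intercept: float
    r_squared: float

    def predict(self, pixels) -> np.ndarray:
        return self.slope * np.asarray(pixels, dtype=float) + self.intercept


def immunoblot_calibration(pixel_values, reference_concs) -> ImmunoblotCalibration:
    """Calibrate densitometry pixel sums against binding-derived cpm/mg."""
    px = np.asarray(pixel_values, dtype=float)
    conc = np.asarray(reference_concs, dtype=float)
    if px.size != conc.size or px.size < 3:
        raise ValueError("need >= 3 paired calibration points")
    res = stats.linregress(px, conc)
    return ImmunoblotCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
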