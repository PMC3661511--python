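"""FRET-based quantification of receptor dimerization in living cells.

A donor- and an acceptor-tagged receptor are co-expressed; the raw FRET
channel mixes true energy transfer with bleed-through from both fluorophores.
After bleed-through correction, each cell's FRET time course (imaged every
minute over 30 min of saturating agonist) is normalized to its pre-stimulus
value and fitted with a sigmoid, whose plateau is the maximal fold-induction
of FRET, f.

Because FRET intensity is proportional to the number of dimers, and a
saturating agonist dose drives essentially complete dimerization, the
pre-stimulus dimer count is D0 = Dmax / f with Dmax = r_total/2.  The mole
fraction of receptors already dimerized before ligand is therefore 1/f, and

    % monomers = 100 * (1 - 1/f).

The proportionality constant between FRET units and dimer counts — and the
~50% probability that a dimer pairs one donor- with one acceptor-tagged
subunit under equimolar co-transfection — multiply both D0 and Dmax and so
cancel exactly in the fold-induction ratio; no absolute calibration of the
FRET channel is needed.  If saturating ligand dimerizes only a fraction
phi_max of the pool, every dimer count above scales by phi_max and the
pre-ligand dimer fraction becomes phi_max/f (the ``complete_dimerization_
fraction`` knob, default 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

log = logging.getLogger(__name__)

TRACE_COLUMNS = ["cell_id", "condition", "time_min", "f_don", "f_acc", "f_raw"]

#: donor-intensity gates used to assign cells to expression populations
DEFAULT_GATES = (600.0, 1200.0)


@dataclass(frozen=True)
class BleedThroughCoefficients:
    """Fractional bleed-through of donor (a) and acceptor (b) into the FRET
    channel.  Defaults are placeholders in a plausible CFP/YFP range and
    should be calibrated per instrument."""

    a: float = 0.5
    b: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.a < 1.0 and 0.0 <= self.b < 1.0):
            raise ValueError("bleed-through coefficients must be in [0, 1)")


@dataclass(frozen=True)
class FretTimeCourseFit:
    fret0: float
    fret_max: float
    max_fold_induction: float
    half_time_min: float
    slope: float

    def __post_init__(self) -> None:
        if not self.fret0 > 0:
            raise ValueError("baseline FRET must be positive")
        if self.max_fold_induction < 1:
            raise ValueError("fold induction cannot be below 1")


@dataclass(frozen=True)
class DimerPartition:
    pct_monomers: float
    pct_dimers: float

    def __post_init__(self) -> None:
        if not (0 <= self.pct_monomers <= 100 and 0 <= self.pct_dimers <= 100):
            raise ValueError("percentages must lie in [0, 100]")
        if abs(self.pct_monomers + self.pct_dimers - 100.0) > 1e-9:
            raise ValueError("monomer and dimer percentages must sum to 100")


def correct_fret(
    f_raw, f_don, f_acc, coeffs: BleedThroughCoefficients | None = None
) -> np.ndarray:
    """Subtract donor and acceptor bleed-through from the raw FRET channel."""
    coeffs = coeffs or BleedThroughCoefficients()
    raw = np.asarray(f_raw, dtype=float)
    don = np.asarray(f_don, dtype=float)
    acc = np.asarray(f_acc, dtype=float)
    corrected = raw - coeffs.a * don - coeffs.b * acc
    n_neg = int((corrected < 0).sum())
    if n_neg:
        log.warning("clipped %d negative corrected-FRET values to 0", n_neg)
        corrected = np.clip(corrected, 0.0, None)
    if np.all(corrected == 0):
        raise ValueError(
            "bleed-through correction removed the entire signal; cannot normalize"
        )
    return corrected


def gate_cells(
    donor_values, gates: tuple[float, float] = DEFAULT_GATES
) -> pd.Series:
    """Assign cells to low / medium / high expression bins by donor signal.

    Bins are left-closed: [0, g1) -> low, [g1, g2) -> medium, >= g2 -> high.
    Missing donor values yield NaN and are logged as excluded.
    """
    s = pd.Series(donor_values, dtype=float)
    g1, g2 = gates
    if not 0 < g1 < g2:
        raise ValueError("gate edges must be positive and increasing")
    out = pd.Series(
        pd.cut(s, bins=[-np.inf, g1, g2, np.inf], right=False,
               labels=["low", "medium", "high"]),
        index=s.index,
    ).astype(object)
    n_missing = int(s.isna().sum())
    if n_missing:
        log.warning("excluded %d cells with missing donor summary", n_missing)
        out[s.isna()] = None
    return out


def fold_induction_series(corrected, cell_id: str | None = None) -> np.ndarray:
    """Normalize a corrected FRET series to its pre-stimulus (first) value."""
    c = np.asarray(corrected, dtype=float)
    if c.size == 0:
        raise ValueError("empty series")
    if c[0] <= 0:
        raise ValueError(
            f"non-positive pre-stimulus FRET for cell {cell_id!r}; cannot normalize"
        )
    return c / c[0]


def fit_time_course(
    time_min, normalized, baseline_fret: float = 1.0
) -> FretTimeCourseFit:
    """Fit a variable-slope sigmoid (bottom fixed at 1) to fold-induction data.

    y(t) = 1 + (top - 1) / (1 + 10^((t_half - t) * slope)); the fitted top is
    the maximal fold-induction.  Near-flat series short-circuit to top = 1.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(normalized, dtype=float)
    if t.size < 10:
        raise ValueError("need >= 10 time points")
    if np.ptp(y) < 1e-9:
        return FretTimeCourseFit(
            fret0=baseline_fret,
            fret_max=baseline_fret * float(y.mean()),
            max_fold_induction=max(float(y.mean()), 1.0),
            half_time_min=float("nan"),
            slope=float("nan"),
        )

    def model(tt, top, t_half, slope):
        return 1.0 + (top - 1.0) / (1.0 + 10.0 ** ((t_half - tt) * slope))

    top0 = max(float(y.max()), 1.01)
    t_half0 = float(t[np.argmin(np.abs(y - (1 + top0) / 2))])
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[top0, t_half0, 0.2],
            bounds=([1.0, t.min() - 30.0, 1e-3], [np.inf, t.max() + 30.0, 10.0]),
            maxfev=20000,
        )
    except RuntimeError:
        # report raw maximum as fallback rather than failing the cell
        log.warning("time-course fit failed; falling back to raw maximum")
        top = max(float(y.max()), 1.0)
        return FretTimeCourseFit(
            fret0=baseline_fret, fret_max=baseline_fret * top,
            max_fold_induction=top, half_time_min=float("nan"), slope=float("nan"),
        )
    top, t_half, slope = popt
    return FretTimeCourseFit(
        fret0=baseline_fret,
        fret_max=baseline_fret * float(top),
        max_fold_induction=float(top),
        half_time_min=float(t_half),
        slope=float(slope),
    )


def partition_from_fold_induction(
    max_fold_induction: float, complete_dimerization_fraction: float = 1.0
) -> DimerPartition:
    """Invert maximal FRET fold-induction into pre-ligand % monomers/dimers.

    Saturating ligand is assumed to dimerize a fraction
    ``complete_dimerization_fraction`` (default: all) of the receptor pool;
    the pre-ligand dimer mole fraction is then phi_max / f.
    """
    f = max_fold_induction
    if f < 1.0:
        raise ValueError(
            "fold induction < 1 contradicts the saturating-ligand assumption"
        )
    if not 0.0 < complete_dimerization_fraction <= 1.0:
        raise ValueError("complete_dimerization_fraction must be in (0, 1]")
    dimer_fraction = complete_dimerization_fraction / f
    return DimerPartition(
        pct_monomers=100.0 * (1.0 - dimer_fraction),
        pct_dimers=100.0 * dimer_fraction,
    )


def analyze_traces(
    traces: pd.DataFrame,
    coeffs: BleedThroughCoefficients | None = None,
    complete_dimerization_fraction: float = 1.0,
) -> pd.DataFrame:
    """Full per-cell pipeline: correct, normalize, fit, invert.

    Returns one row per cell with the donor gate, fitted fold-induction and
    the inferred pre-ligand monomer/dimer percentages.
    """
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    rows = []
    for cell_id, g in traces.groupby("cell_id", sort=True):
        g = g.sort_values("time_min")
        corrected = correct_fret(g["f_raw"], g["f_don"], g["f_acc"], coeffs)
        norm = fold_induction_series(corrected, cell_id=str(cell_id))
        fit = fit_time_course(g["time_min"].to_numpy(), norm,
                              baseline_fret=float(corrected[0]))
        part = partition_from_fold_induction(
            max(fit.max_fold_induction, 1.0), complete_dimerization_fraction
        )
        rows.append(
            {
                "cell_id": cell_id,
                "condition": g["condition"].iloc[0],
                "donor_summary": float(g["f_don"].iloc[-1]),
                "max_fold_induction": fit.max_fold_induction,
                "pct_monomers": part.pct_monomers,
                "pct_dimers": part.pct_dimers,
            }
        )
    out = pd.DataFrame(rows)
    out["gate"] = gate_cells(out["donor_summary"]).to_numpy()
    return out
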