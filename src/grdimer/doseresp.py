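"""Transactivation dose-response analysis.

Promoter-reporter (luciferase) or qPCR readouts over a log dose grid are fit
with the four-parameter logistic (4PL) on log10 molar concentration:

    y = bottom + (top - bottom) / (1 + 10^((logEC50 - log c) * hill))

yielding basal induction (bottom), maximal induction (top), efficacy
(top - bottom), fold-induction (top/bottom) and potency (EC50).  The Hill
slope is either fixed at 1 (potency comparisons) or free (slope analysis).
Vehicle wells (conc = 0) anchor the lower asymptote and are placed one
decade below the lowest tested dose on the log axis.

Potency shifts between receptor-expression conditions are reported as EC50
ratios with seeded bootstrap confidence intervals (replicate resampling),
and partial-agonist "bio-character" as each ligand's efficacy relative to
the reference full agonist at the same condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

DOSE_COLUMNS = ["ligand", "conc_M", "response", "replicate", "condition"]


@dataclass(frozen=True)
class FourPLFit:
    bottom: float
    top: float
    log_ec50: float  # log10 M
    hill: float
    ec50_in_range: bool
    slope_mode: str

    def __post_init__(self) -> None:
        if self.top < self.bottom or self.bottom < 0:
            raise ValueError("requires top >= bottom >= 0")

    @property
    def ec50(self) -> float:
        return 10.0**self.log_ec50

    @property
    def efficacy(self) -> float:
        return self.top - self.bottom

    @property
    def fold_induction(self) -> float:
        if self.bottom <= 0:
            return float("inf")
        return self.top / self.bottom

    def predict(self, conc_m) -> np.ndarray:
        logc = np.log10(np.asarray(conc_m, dtype=float))
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** ((self.log_ec50 - logc) * self.hill)
        )


def normalize_response(rlu, protein_mg) -> np.ndarray:
    """Normalize luminescence to protein mass (RLU/mg)."""
    rlu = np.asarray(rlu, dtype=float)
    protein = np.asarray(protein_mg, dtype=float)
    if np.any(protein <= 0):
        raise ValueError("protein_mg must be positive")
    return rlu / protein


def _log_conc_with_vehicle(conc_m: np.ndarray) -> np.ndarray:
    """Map concentrations to log10 M, placing vehicle a decade below range."""
    conc = np.asarray(conc_m, dtype=float)
    pos = conc[conc > 0]
    if pos.size == 0:
        raise ValueError("no positive concentrations")
    pseudo = np.log10(pos.min()) - 1.0
    out = np.where(conc > 0, np.log10(np.where(conc > 0, conc, 1.0)), pseudo)
    return out


def fit_4pl(dataset: pd.DataFrame, slope_mode: str = "fixed1") -> FourPLFit:
    """Least-squares 4PL fit of a single ligand x condition dataset.

    ``slope_mode`` is ``"fixed1"`` (Hill fixed at 1) or ``"variable"``.
    An EC50 outside the tested concentration range is flagged, not raised.
    """
    missing = [c for c in ("conc_M", "response") if c not in dataset.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    if slope_mode not in ("fixed1", "variable"):
        raise ValueError("slope_mode must be 'fixed1' or 'variable'")
    conc = dataset["conc_M"].to_numpy(dtype=float)
    y = dataset["response"].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValueError("responses must be non-negative")
    if np.unique(conc[conc > 0]).size < 6:
        raise ValueError("need >= 6 distinct positive concentrations")
    x = _log_conc_with_vehicle(conc)

    b0 = max(float(np.median(y[conc == 0])) if (conc == 0).any() else float(y.min()),
             1e-9)
    t0 = max(float(y.max()), b0 * 1.01)
    e0 = float(x[np.argmin(np.abs(y - (b0 + t0) / 2))])

    if slope_mode == "fixed1":
        def model(lx, bottom, top, logec50):
            return bottom + (top - bottom) / (1.0 + 10.0 ** (logec50 - lx))
        p0 = [b0, t0, e0]
        lb = [0.0, 0.0, x.min() - 6.0]
        ub = [np.inf, np.inf, x.max() + 6.0]
    else:
        def model(lx, bottom, top, logec50, hill):
            return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - lx) * hill))
        p0 = [b0, t0, e0, 1.0]
        lb = [0.0, 0.0, x.min() - 6.0, 0.05]
        ub = [np.inf, np.inf, x.max() + 6.0, 10.0]

    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=(lb, ub),
                                     maxfev=20000)
    except RuntimeError as err:
        raise ValueError(f"4PL fit did not converge: {err}") from err
    bottom, top, logec50 = popt[:3]
    hill = popt[3] if slope_mode == "variable" else 1.0
    pos = conc[conc > 0]
    in_range = bool(np.log10(pos.min()) <= logec50 <= np.log10(pos.max()))
    # numerical noise can leave top a hair under bottom on flat data
    top = max(float(top), float(bottom))
    return FourPLFit(bottom=float(bottom), top=top, log_ec50=float(logec50),
                     hill=float(hill), ec50_in_range=in_range,
                     slope_mode=slope_mode)


@dataclass(frozen=True)
class PotencyShift:
    reference: str
    ratios: Mapping[str, float]          # EC50(reference) / EC50(condition)
    ci_low: Mapping[str, float]
    ci_high: Mapping[str, float]


def potency_shift(
    datasets: Mapping[str, pd.DataFrame],
    reference: str,
    slope_mode: str = "fixed1",
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> PotencyShift:
    """EC50 fold-shifts of each condition relative to a reference.

    A ratio > 1 means the condition is more potent (lower EC50) than the
    reference.  Confidence intervals come from seeded bootstrap resampling
    of replicates within each concentration.
    """
    if reference not in datasets:
        raise ValueError(f"reference condition {reference!r} not in datasets")
    fits = {k: fit_4pl(df, slope_mode) for k, df in datasets.items()}
    ref_ec50 = fits[reference].ec50
    ratios = {k: ref_ec50 / f.ec50 for k, f in fits.items()}

    rng = np.random.default_rng(seed)
    boot: dict[str, list[float]] = {k: [] for k in datasets}
    alpha = (1.0 - ci) / 2.0
    for _ in range(n_boot):
        sample_ec50 = {}
        ok = True
        for k, df in datasets.items():
            res = (
                df.groupby("conc_M", group_keys=False)
                .sample(frac=1.0, replace=True,
                        random_state=int(rng.integers(2**31)))
                .reset_index(drop=True)
            )
            try:
                sample_ec50[k] = fit_4pl(res, slope_mode).ec50
            except ValueError:
                ok = False
                break
        if not ok:
            continue
        for k in datasets:
            boot[k].append(sample_ec50[reference] / sample_ec50[k])
    ci_low = {
        k: float(np.quantile(v, alpha)) if v else float("nan")
        for k, v in boot.items()
    }
    ci_high = {
        k: float(np.quantile(v, 1 - alpha)) if v else float("nan")
        for k, v in boot.items()
    }
    return PotencyShift(reference=reference, ratios=ratios,
                        ci_low=ci_low, ci_high=ci_high)


def bio_character(fit_ligand: FourPLFit, fit_reference: FourPLFit) -> float:
    """Ligand's maximal efficacy as % of the reference full agonist's."""
    if fit_reference.efficacy <= 0:
        raise ValueError("reference efficacy must be positive")
    return 100.0 * fit_ligand.efficacy / fit_reference.efficacy


def single_dose_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean response and fold-over-vehicle per ligand at a single dose."""
    if not (dataset["conc_M"] == 0).any():
        raise ValueError("vehicle (conc_M = 0) rows are required")
    vehicle = dataset.loc[dataset["conc_M"] == 0, "response"].mean()
    if vehicle <= 0:
        raise ValueError("vehicle response must be positive")
    out = (
        dataset[dataset["conc_M"] > 0]
        .groupby("ligand")["response"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    out["fold_over_vehicle"] = out["mean"] / vehicle
    return out


def qpcr_relative_expression(
    ct_target, ct_housekeeping, ct_target_cal: float, ct_housekeeping_cal: float
):
    """Relative expression by the delta-delta-Ct method.

    fold = 2^-((Ct_t - Ct_h) - (Ct_t,cal - Ct_h,cal)).
    """
    ct_t = np.asarray(ct_target, dtype=float)
    ct_h = np.asarray(ct_housekeeping, dtype=float)
    if not (np.all(np.isfinite(ct_t)) and np.all(np.isfinite(ct_h))
            and np.isfinite(ct_target_cal) and np.isfinite(ct_housekeeping_cal)):
        raise ValueError("Ct values must be finite")
    ddct = (ct_t - ct_h) - (ct_target_cal - ct_housekeeping_cal)
    return 2.0 ** (-ddct)
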