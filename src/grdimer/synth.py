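"""Seeded synthetic-data generators for every assay in the pipeline.

Each generator emulates one experimental design — whole-cell saturation
binding with matched total/nonspecific tubes, per-cell FRET time courses,
triplicate dose-response plates on a 10^-14 to 10^-5 M grid, and co-IP /
ChIP / endogenous-gene qPCR tables — with the statistical structure the
corresponding analysis assumes, and programmed truths taken from the
expression presets.  Noise laws: Poisson on expected scintillation counts
plus Gaussian background; multiplicative log-normal on luminescence and
band/qPCR abundances; additive Gaussian (a fraction of signal) on FRET
channels; Gaussian on Ct values.  All randomness flows through a
numpy Generator seeded per call, so identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fret import BleedThroughCoefficients
from .presets import Preset, get_preset
from .equilibrium import solve_equilibrium
from .units import ConversionConstants

__all__ = [
    "NoiseModel",
    "DEFAULT_DOSE_GRID_M",
    "DEFAULT_LHOT_GRID_NM",
    "gen_saturation",
    "gen_fret",
    "gen_dose_response",
    "gen_gilz_qpcr",
    "gen_enrichment",
]

#: the transactivation dose grid: decade steps from 10 fM to 10 uM
DEFAULT_DOSE_GRID_M = tuple(10.0 ** np.arange(-14, -4).astype(float))

#: hot-ligand grid (nM) bracketing the expected affinity
DEFAULT_LHOT_GRID_NM = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 150.0)


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion parameters for all simulated readouts."""

    poisson_counts: bool = True
    cpm_background_sd: float = 10.0
    rlu_cv: float = 0.15
    fret_sd_frac: float = 0.03
    ct_sd: float = 0.2
    densitometry_cv: float = 0.10

    def __post_init__(self) -> None:
        for name in ("cpm_background_sd", "rlu_cv", "fret_sd_frac",
                     "ct_sd", "densitometry_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free variant (for truth-recovery checks)."""
        return cls(poisson_counts=False, cpm_background_sd=0.0, rlu_cv=0.0,
                   fret_sd_frac=0.0, ct_sd=0.0, densitometry_cv=0.0)

    def with_(self, **kw) -> "NoiseModel":
        return replace(self, **kw)


def _as_preset(preset: str | Preset) -> Preset:
    return get_preset(preset) if isinstance(preset, str) else preset


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# saturation binding


def expected_specific_cpm_per_mg(
    preset: str | Preset, l_hot_nm, constants: ConversionConstants | None = None
) -> np.ndarray:
    """Noiseless specific binding (cpm/mg) from the equilibrium model.

    Bound ligand at each dose is scaled so that full receptor saturation
    corresponds to the preset's bulk density in fmol/mg, then converted to
    counts with the documented specific activity and counting efficiency.
    """
    p = _as_preset(preset)
    cc = constants or ConversionConstants()
    l = np.asarray(l_hot_nm, dtype=float)
    bound = np.array(
        [solve_equilibrium(p.params, p.r_total_nM, x).bound_ligand for x in l]
    )
    fmol_per_mg = p.bulk_conc_fmol_per_mg * bound / p.r_total_nM
    return fmol_per_mg * cc.cpm_per_fmol


def gen_saturation(
    preset: str | Preset,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    l_hot_grid_nm=DEFAULT_LHOT_GRID_NM,
    protein_mg: float = 0.25,
    nonspecific_fraction_at_max: float = 0.20,
) -> pd.DataFrame:
    """Simulate matched total / nonspecific saturation-binding tubes.

    Nonspecific binding is linear in the hot-ligand dose, with slope chosen
    so it makes up ``nonspecific_fraction_at_max`` of total binding at the
    highest dose.
    """
    p = _as_preset(preset)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    l = np.asarray(l_hot_grid_nm, dtype=float)
    spec_mg = expected_specific_cpm_per_mg(p, l)
    f = nonspecific_fraction_at_max
    ns_slope = (f / (1.0 - f)) * spec_mg[-1] / l[-1]  # cpm/mg per nM
    rows = []
    for rep in range(1, n_replicates + 1):
        total_mu = (spec_mg + ns_slope * l) * protein_mg
        ns_mu = ns_slope * l * protein_mg
        if noise.poisson_counts:
            total = rng.poisson(total_mu).astype(float)
            ns = rng.poisson(ns_mu).astype(float)
        else:
            total, ns = total_mu.copy(), ns_mu.copy()
        if noise.cpm_background_sd > 0:
            total += rng.normal(0, noise.cpm_background_sd, l.size)
            ns += rng.normal(0, noise.cpm_background_sd, l.size)
        for i, x in enumerate(l):
            rows.append(
                {"l_hot_nM": x, "total_cpm": max(total[i], 0.0),
                 "nonspecific_cpm": max(ns[i], 0.0), "protein_mg": protein_mg,
                 "replicate": rep, "condition": p.name}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FRET time courses


def gen_fret(
    preset: str | Preset,
    noise: NoiseModel | None = None,
    n_cells: int = 50,
    seed: int = 0,
    coeffs: BleedThroughCoefficients | None = None,
    t_half_min: float = 10.0,
    slope_per_min: float = 0.7,
    fret_per_donor_unit: float = 1.0,
) -> pd.DataFrame:
    """Simulate per-cell donor/acceptor/raw-FRET traces, 0-30 min.

    The programmed dimer count rises along the same variable-slope sigmoid
    the analysis fits, from a pre-ligand fraction phi of the pool (the
    preset truth) to complete dimerization, so the true FRET fold-induction
    is 1/phi.  Donor intensity per cell is drawn inside the preset's
    expression gate; the raw FRET channel mixes true FRET with donor and
    acceptor bleed-through before channel noise is added.
    """
    p = _as_preset(preset)
    noise = noise or NoiseModel()
    coeffs = coeffs or BleedThroughCoefficients()
    rng = np.random.default_rng(seed)
    phi = p.fret_dimer_fraction
    gate_range = {
        "low": (300.0, 550.0), "medium": (700.0, 1100.0), "high": (1300.0, 1800.0)
    }[p.name.split("_")[1]]
    t = np.arange(0.0, 31.0)
    sigma_t = 1.0 / (1.0 + 10.0 ** ((t_half_min - t) * slope_per_min))
    fold = 1.0 + (1.0 / phi - 1.0) * sigma_t  # true FRET fold-induction
    rows = []
    for cell in range(1, n_cells + 1):
        don = rng.uniform(*gate_range)
        acc = don * rng.uniform(0.8, 1.0)
        # true FRET intensity ~ dimer count; pre-ligand dimers phi*R/2
        fret0 = fret_per_donor_unit * phi * don / 2.0
        fret_true = fret0 * fold
        don_t = np.full(t.size, don)
        acc_t = np.full(t.size, acc)
        raw = fret_true + coeffs.a * don_t + coeffs.b * acc_t
        if noise.fret_sd_frac > 0:
            don_t = don_t + rng.normal(0, noise.fret_sd_frac * don, t.size)
            acc_t = acc_t + rng.normal(0, noise.fret_sd_frac * acc, t.size)
            raw = raw + rng.normal(0, noise.fret_sd_frac * raw)
        for i in range(t.size):
            rows.append(
                {"cell_id": f"{p.name}_c{cell:03d}", "condition": p.name,
                 "time_min": t[i], "f_don": max(don_t[i], 0.0),
                 "f_acc": max(acc_t[i], 0.0), "f_raw": max(raw[i], 0.0)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dose-response (reporter and endogenous gene)


def gen_dose_response(
    preset: str | Preset,
    ligand: str = "DEX",
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    dose_grid_m=DEFAULT_DOSE_GRID_M,
    protein_mg: float = 0.5,
) -> pd.DataFrame:
    """Simulate a triplicate luciferase dose-response plate (plus vehicle).

    Responses are 4PL truth values under multiplicative log-normal noise;
    raw RLU and protein mass are emitted alongside the normalized response.
    """
    p = _as_preset(preset)
    noise = noise or NoiseModel()
    if ligand not in p.dose_response:
        raise KeyError(f"no programmed truth for ligand {ligand!r} in {p.name}")
    truth = p.dose_response[ligand]
    rng = np.random.default_rng(seed)
    conc = np.concatenate([[0.0], np.asarray(dose_grid_m, dtype=float)])
    rows = []
    for rep in range(1, n_replicates + 1):
        for c in conc:
            if c == 0:
                mu = truth.bottom
            else:
                mu = truth.bottom + (truth.top - truth.bottom) / (
                    1.0 + 10.0 ** ((np.log10(truth.ec50_M) - np.log10(c)) * truth.hill)
                )
            resp = mu * _lognormal_factor(rng, noise.rlu_cv, None)
            rows.append(
                {"ligand": ligand, "conc_M": c, "rlu": resp * protein_mg,
                 "protein_mg": protein_mg, "response": resp,
                 "replicate": rep, "condition": p.name}
            )
    return pd.DataFrame(rows)


def gen_gilz_qpcr(
    preset: str | Preset,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    dose_grid_m=DEFAULT_DOSE_GRID_M,
    ct_housekeeping: float = 18.0,
    dct_calibrator: float = 6.0,
) -> pd.DataFrame:
    """Simulate endogenous-gene qPCR Ct tables over the dose grid.

    The programmed truth is a 4PL in fold-expression relative to vehicle;
    target Ct values are back-computed through the delta-delta-Ct relation
    (one cycle = a factor of 2) and Gaussian cycle noise is added to both
    target and housekeeping channels.
    """
    p = _as_preset(preset)
    noise = noise or NoiseModel()
    truth = p.gilz
    rng = np.random.default_rng(seed)
    conc = np.concatenate([[0.0], np.asarray(dose_grid_m, dtype=float)])
    rows = []
    for rep in range(1, n_replicates + 1):
        for c in conc:
            if c == 0:
                fold = truth.bottom
            else:
                fold = truth.bottom + (truth.top - truth.bottom) / (
                    1.0 + 10.0 ** ((np.log10(truth.ec50_M) - np.log10(c)) * truth.hill)
                )
            # calibrator (vehicle) is defined to have fold = bottom; express
            # everything relative to a fold-1 reference so vehicle recovers
            # the programmed basal
            ct_h = ct_housekeeping + rng.normal(0, noise.ct_sd)
            ct_t = (ct_housekeeping + dct_calibrator - np.log2(fold)
                    + rng.normal(0, noise.ct_sd))
            rows.append(
                {"ligand": "DEX", "conc_M": c, "ct_target": ct_t,
                 "ct_housekeeping": ct_h, "replicate": rep, "condition": p.name}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# co-IP and ChIP


def gen_enrichment(
    preset: str | Preset,
    assay: str,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate co-IP densitometry, ChIP-qPCR, or endogenous-gene qPCR.

    * ``coip``: Flag (bait) and GFP (pull-down) band pixel sums per
      treatment; the programmed normalized ratio is the preset percentage of
      a reference ratio of 0.8 (the reference condition's value).
    * ``chip``: pull-down and input qPCR abundances for vehicle and agonist,
      plus the no-receptor baseline rows; programmed loading is relative to
      that baseline.
    * ``gilz_qpcr``: delegates to :func:`gen_gilz_qpcr`.
    """
    p = _as_preset(preset)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    if assay == "gilz_qpcr":
        return gen_gilz_qpcr(p, noise=noise, n_replicates=n_replicates, seed=seed)
    if assay == "coip":
        ref_ratio = 0.8  # normalized GFP/Flag ratio of the reference condition
        rows = []
        for treatment, pct in p.coip_pct_of_reference.items():
            for rep in range(1, n_replicates + 1):
                flag = 10000.0 * _lognormal_factor(rng, noise.densitometry_cv, None)
                gfp = (pct / 100.0) * ref_ratio * flag * _lognormal_factor(
                    rng, noise.densitometry_cv, None
                )
                # IgG negative-control channel: modeled but never subtracted
                igg = 50.0 * _lognormal_factor(rng, noise.densitometry_cv, None)
                rows.append(
                    {"condition": p.name, "construct": p.name.split("_")[0],
                     "treatment": treatment, "replicate": rep,
                     "flag_band": flag, "gfp_band": gfp, "igg_band": igg}
                )
        return pd.DataFrame(rows)
    if assay == "chip":
        baseline_ratio = 0.01  # pulldown/input of the no-receptor vehicle
        rows = []
        conditions = [
            ("no_gr", "EtOH", 1.0),
            (p.name, "EtOH", p.chip_vehicle_loading),
            (p.name, "DEX", p.chip_dex_loading),
        ]
        for cond, treatment, loading in conditions:
            for rep in range(1, n_replicates + 1):
                inp = 100.0 * _lognormal_factor(rng, noise.densitometry_cv, None)
                pull = loading * baseline_ratio * inp * _lognormal_factor(
                    rng, noise.densitometry_cv, None
                )
                rows.append(
                    {"condition": cond, "construct": p.name.split("_")[0],
                     "treatment": treatment, "replicate": rep,
                     "pulldown_qpcr": pull, "input_qpcr": inp}
                )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown assay {assay!r}; use coip, chip or gilz_qpcr")
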