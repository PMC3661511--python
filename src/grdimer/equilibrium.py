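"""Mass-action model of receptor monomer-dimer equilibrium with ligand.

Five receptor species are tracked: free monomer M, liganded monomer ML,
unliganded dimer D, singly liganded dimer DL and doubly liganded dimer DL2.
Free ligand L is clamped (whole-cell binding in a large medium volume; no
depletion).  Macroscopic dissociation constants, all in nM:

    kdA : M + L <-> ML           kdA = [M][L]/[ML]
    kdC : 2M <-> D               kdC = [M]^2/[D]
    kdD1: D + L <-> DL           kdD1 = [D][L]/[DL]
    kdD2: DL + L <-> DL2         kdD2 = [DL][L]/[DL2]
    kdB : 2ML <-> DL2            kdB = [ML]^2/[DL2]   (derived)

The two routes from 2M + 2L to DL2 (bind-then-dimerize vs dimerize-then-bind)
form a thermodynamic cycle, so detailed balance fixes

    kdA^2 * kdB = kdC * kdD1 * kdD2,

and kdB is always computed from the other four constants, never set directly.
Because the constants are macroscopic, two identical independent sites on the
dimer give kdD2/kdD1 = 4 (statistical factor); macroscopic positive
cooperativity therefore requires kdD2/kdD1 < 1/4, not merely < 1.

Given clamped L, every species concentration follows from [M], and receptor
mass balance is a quadratic in [M]:

    r_total = m*(1 + l/kdA) + 2*(m^2/kdC)*(1 + l/kdD1 + l^2/(kdD1*kdD2))

whose unique positive root is taken with the cancellation-safe form
m = 2 r / (b + sqrt(b^2 + 4 a r)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "EquilibriumParams",
    "SpeciesState",
    "DnaAffinityParams",
    "solve_equilibrium",
    "specific_binding_curve",
    "dimer_fraction",
    "promoter_occupancy",
    "predicted_dose_response",
    "calibrate_presets",
    "CalibrationResult",
]

#: gas constant in kcal/(mol*K), for reporting Kd as a binding free energy
R_KCAL = 1.987204259e-3


@dataclass(frozen=True)
class EquilibriumParams:
    """Dissociation constants of the monomer-dimer-ligand cycle (nM)."""

    kdA: float
    kdC: float
    kdD1: float
    kdD2: float
    kdB: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("kdA", "kdC", "kdD1", "kdD2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        object.__setattr__(
            self, "kdB", self.kdC * self.kdD1 * self.kdD2 / self.kdA**2
        )

    @property
    def cooperativity_factor(self) -> float:
        """kdD2/kdD1; macroscopically positively cooperative iff < 1/4."""
        return self.kdD2 / self.kdD1

    @property
    def is_positively_cooperative(self) -> bool:
        return self.cooperativity_factor < 0.25

    def delta_g(self, temperature_k: float = 310.15) -> dict[str, float]:
        """Binding free energies -RT ln(Kd/1 nM in M units), kcal/mol."""
        rt = R_KCAL * temperature_k
        return {
            name: -rt * math.log(getattr(self, name) * 1e-9)
            for name in ("kdA", "kdB", "kdC", "kdD1", "kdD2")
        }

    def with_impaired_dimerization(self, factor: float) -> "EquilibriumParams":
        """Weaken dimerization (the dimerization-loop mutant) by ``factor``.

        kdC is scaled directly; kdB follows through the cycle constraint, so
        both unliganded and liganded dimerization weaken together.
        """
        if factor <= 0:
            raise ValueError("impairment factor must be positive")
        return EquilibriumParams(self.kdA, self.kdC * factor, self.kdD1, self.kdD2)

    def to_dict(self) -> dict[str, float]:
        return {
            "kdA_nM": self.kdA,
            "kdC_nM": self.kdC,
            "kdD1_nM": self.kdD1,
            "kdD2_nM": self.kdD2,
            "kdB_nM": self.kdB,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "EquilibriumParams":
        return cls(d["kdA_nM"], d["kdC_nM"], d["kdD1_nM"], d["kdD2_nM"])


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (nM) of the five receptor species."""

    m: float
    ml: float
    d: float
    dl: float
    dl2: float
    l_free: float
    r_total: float

    def __post_init__(self) -> None:
        for name in ("m", "ml", "d", "dl", "dl2", "l_free", "r_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def monomer_moles(self) -> float:
        return self.m + self.ml

    @property
    def dimer_moles(self) -> float:
        """Receptor moles tied up in dimeric species (monomer-equivalents)."""
        return 2.0 * (self.d + self.dl + self.dl2)

    @property
    def bound_ligand(self) -> float:
        """Specifically bound ligand, nM: one per ML and DL, two per DL2."""
        return self.ml + self.dl + 2.0 * self.dl2

    def mass_balance_residual(self) -> float:
        if self.r_total == 0:
            return 0.0
        return abs(self.monomer_moles + self.dimer_moles - self.r_total) / self.r_total


def solve_equilibrium(
    params: EquilibriumParams, r_total: float, l_free: float
) -> SpeciesState:
    """Solve the clamped-ligand equilibrium for a total receptor pool.

    Returns the unique non-negative solution of the quadratic receptor mass
    balance.  ``r_total`` is in monomer-equivalents, nM.
    """
    if r_total < 0 or l_free < 0:
        raise ValueError("r_total and l_free must be non-negative")
    if r_total == 0:
        return SpeciesState(0.0, 0.0, 0.0, 0.0, 0.0, l_free, 0.0)

    l = l_free
    b = 1.0 + l / params.kdA
    a = (2.0 / params.kdC) * (
        1.0 + l / params.kdD1 + l * l / (params.kdD1 * params.kdD2)
    )
    # unique positive root of a*m^2 + b*m - r = 0, written to avoid
    # catastrophic cancellation when a*r << b^2
    m = 2.0 * r_total / (b + math.sqrt(b * b + 4.0 * a * r_total))
    d = m * m / params.kdC
    ml = m * l / params.kdA
    dl = d * l / params.kdD1
    dl2 = dl * l / params.kdD2
    return SpeciesState(m, ml, d, dl, dl2, l, r_total)


def dimer_fraction(params: EquilibriumParams, r_total: float, l_free: float) -> float:
    """Fraction of receptor moles residing in dimeric species, in [0, 1]."""
    if r_total == 0:
        return 0.0
    state = solve_equilibrium(params, r_total, l_free)
    return state.dimer_moles / r_total


def specific_binding_curve(
    params: EquilibriumParams, r_total: float, l_grid: Sequence[float]
) -> np.ndarray:
    """Specifically bound ligand (nM) across a free-ligand grid.

    Returns an array of shape (n, 2) with columns (l_free, bound).
    """
    l_grid = np.asarray(l_grid, dtype=float)
    if l_grid.size == 0:
        raise ValueError("ligand grid is empty")
    if np.any(l_grid < 0) or np.any(np.diff(l_grid) < 0):
        raise ValueError("ligand grid must be non-negative and sorted")
    bound = np.array(
        [solve_equilibrium(params, r_total, l).bound_ligand for l in l_grid]
    )
    return np.column_stack([l_grid, bound])


# ---------------------------------------------------------------------------
# DNA binding and transactivation readout


@dataclass(frozen=True)
class DnaAffinityParams:
    """Single-GRE competitive binding affinities and activity weights.

    Defaults: monomer 62 nM and unliganded dimer 1.21 nM are literature
    electromobility-shift values; liganded dimer 0.23 nM likewise; the
    liganded-monomer 30 nM default is an assumption chosen to respect the
    affinity hierarchy  liganded dimer < unliganded dimer <= liganded
    monomer < unliganded monomer (smaller Kd = tighter binding).

    Activity weights translate site occupancy into a transcriptional
    readout; with a nonzero unliganded-dimer weight, preformed dimers prime
    basal transactivation before any ligand is added.
    """

    kd_dna_monomer: float = 62.0
    kd_dna_dimer_unliganded: float = 1.21
    kd_dna_dimer_liganded: float = 0.23
    kd_dna_monomer_liganded: float = 30.0
    activity_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "monomer": 0.0,
            "monomer_liganded": 0.0,
            "dimer_unliganded": 0.2,
            "dimer_liganded": 1.0,
        }
    )

    def __post_init__(self) -> None:
        for name in (
            "kd_dna_monomer",
            "kd_dna_dimer_unliganded",
            "kd_dna_dimer_liganded",
            "kd_dna_monomer_liganded",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(w < 0 for w in self.activity_weights.values()):
            raise ValueError("activity weights must be non-negative")

    def kd_map(self) -> dict[str, float]:
        return {
            "monomer": self.kd_dna_monomer,
            "monomer_liganded": self.kd_dna_monomer_liganded,
            "dimer_unliganded": self.kd_dna_dimer_unliganded,
            "dimer_liganded": self.kd_dna_dimer_liganded,
        }


def _species_classes(state: SpeciesState) -> dict[str, float]:
    return {
        "monomer": state.m,
        "monomer_liganded": state.ml,
        "dimer_unliganded": state.d,
        "dimer_liganded": state.dl + state.dl2,
    }


def promoter_occupancy(
    params: EquilibriumParams, dna: DnaAffinityParams, state: SpeciesState
) -> tuple[dict[str, float], float]:
    """Competitive occupancy of one response-element site, plus activity.

    occ_s = ([s]/Kd_s) / (1 + sum_s' [s']/Kd_s'); occupancies sum to <= 1.
    Activity is the weight-averaged occupancy.
    """
    conc = _species_classes(state)
    kds = dna.kd_map()
    ratios = {s: conc[s] / kds[s] for s in conc}
    denom = 1.0 + sum(ratios.values())
    occ = {s: ratios[s] / denom for s in conc}
    activity = sum(dna.activity_weights.get(s, 0.0) * occ[s] for s in occ)
    return occ, activity


def predicted_dose_response(
    params: EquilibriumParams,
    dna: DnaAffinityParams,
    r_total: float,
    l_grid: Sequence[float],
) -> np.ndarray:
    """Transactivation activity over a ligand grid; columns (l, activity).

    With a nonzero unliganded-dimer weight, activity at l=0 reflects basal
    priming by preformed dimers and grows with the receptor pool.
    """
    l_grid = np.asarray(l_grid, dtype=float)
    if l_grid.size == 0:
        raise ValueError("ligand grid is empty")
    activity = np.array(
        [
            promoter_occupancy(params, dna, solve_equilibrium(params, r_total, l))[1]
            for l in l_grid
        ]
    )
    return np.column_stack([l_grid, activity])


# ---------------------------------------------------------------------------
# Calibration of parameters to observed summaries


@dataclass
class CalibrationResult:
    params: EquilibriumParams
    r_totals: dict[str, float]
    targets: dict[str, float]
    achieved: dict[str, float]
    residuals: dict[str, float]
    feasible: bool
    max_abs_log_residual: float

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "r_totals_nM": self.r_totals,
            "targets": self.targets,
            "achieved": self.achieved,
            "log_residuals": self.residuals,
            "feasible": self.feasible,
            "max_abs_log_residual": self.max_abs_log_residual,
        }


DEFAULT_CALIBRATION_TARGETS: dict[str, float] = {
    # pre-ligand dimer mole fractions at the three wild-type presets
    "dimer_fraction_low": 1.0 / 3.0,
    "dimer_fraction_medium": 2.0 / 3.0,
    "dimer_fraction_high": 2.0 / 3.0,
    # one-site fit of the high-preset saturation curve, nM
    "apparent_kd_high": 16.8,
    # variable-slope Hill fit of the same curve
    "hill_slope_high": 1.72,
}

#: receptor pools (nM) at the three wild-type expression presets, from the
#: fmol/mg -> nM conversion of the transfection-corrected densities
DEFAULT_R_TOTALS: dict[str, float] = {}


def _default_r_totals() -> dict[str, float]:
    from .units import ConversionConstants, fmol_per_mg_to_nm, transfection_correction

    cc = ConversionConstants()
    bulk = {"low": 67.0, "medium": 152.6, "high": 283.9}
    return {
        k: fmol_per_mg_to_nm(transfection_correction(v, cc.transfection_efficiency), cc)
        for k, v in bulk.items()
    }


def _observables(
    params: EquilibriumParams, r_totals: Mapping[str, float]
) -> dict[str, float]:
    from .binding import fit_hill, fit_one_site

    obs = {
        f"dimer_fraction_{k}": dimer_fraction(params, r, 0.0)
        for k, r in r_totals.items()
    }
    # evaluate the apparent Kd and Hill slope on the same hot-ligand design
    # the binding assay uses: fitted summaries of a cooperative curve depend
    # on the dose grid, and the observed values come from that design
    from .synth import DEFAULT_LHOT_GRID_NM

    l_grid = np.asarray(DEFAULT_LHOT_GRID_NM, dtype=float)
    curve = specific_binding_curve(params, r_totals["high"], l_grid)
    one = fit_one_site(curve[:, 0], curve[:, 1])
    hill = fit_hill(np.log10(curve[:, 0]), curve[:, 1])
    obs["apparent_kd_high"] = one.kd
    obs["hill_slope_high"] = hill.hill_slope
    return obs


def calibrate_presets(
    targets: Mapping[str, float] | None = None,
    r_totals: Mapping[str, float] | None = None,
    x0: Sequence[float] = (30.0, 40.0, 40.0, 1.0),
    feasibility_tol: float = 0.35,
) -> CalibrationResult:
    """Fit (kdA, kdC, kdD1, kdD2) to observed equilibrium summaries.

    Minimizes squared log-ratios between model observables and targets with a
    deterministic trust-region least-squares solve from the fixed starting
    point ``x0`` (nM).  The receptor pools at each preset are inputs, not fit
    parameters.  If the largest |log residual| exceeds ``feasibility_tol``
    the target combination is flagged infeasible; the best-effort fit is
    still returned, never silently discarded.
    """
    targets = dict(targets or DEFAULT_CALIBRATION_TARGETS)
    r_totals = dict(r_totals or _default_r_totals())

    keys = sorted(targets)

    def resid(log10_k: np.ndarray) -> np.ndarray:
        p = EquilibriumParams(*(10.0**log10_k))
        obs = _observables(p, r_totals)
        return np.array([math.log(obs[k] / targets[k]) for k in keys])

    sol = least_squares(
        resid,
        np.log10(np.asarray(x0, dtype=float)),
        bounds=(-3.0, 6.0),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    params = EquilibriumParams(*(10.0**sol.x))
    achieved = _observables(params, r_totals)
    residuals = {k: math.log(achieved[k] / targets[k]) for k in keys}
    max_res = max(abs(v) for v in residuals.values())
    return CalibrationResult(
        params=params,
        r_totals=r_totals,
        targets=targets,
        achieved={k: achieved[k] for k in keys},
        residuals=residuals,
        feasible=max_res <= feasibility_tol,
        max_abs_log_residual=max_res,
    )
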