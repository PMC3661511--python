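"""Unit conversions for whole-cell radioligand binding.

Scintillation counts (cpm) are converted to receptor densities (fmol/mg
protein), corrected for the fraction of cells actually transfected, and
expressed either as receptors per cell or as an intracellular concentration
in nM.  The chain is

    cpm/mg --(counting efficiency, specific activity)--> fmol/mg (bulk)
           --(/ transfection efficiency)--> fmol/mg in transfected cells
           --(x protein per cell)--> fmol/cell --> molecules/cell
           --(/ cell volume)--> nM

Dimensional analysis of the first step: a specific activity of S Ci/mmol
equals S * 2.22e12 dpm/Ci * 1e-12 mmol/fmol = 2.22*S dpm/fmol; multiplying
by the counting efficiency gives cpm/fmol, and dividing cpm/mg by cpm/fmol
gives fmol/mg.
"""

from __future__ import annotations

from dataclasses import dataclass

AVOGADRO = 6.02214076e23
DPM_PER_CI = 2.22e12


@dataclass(frozen=True)
class ConversionConstants:
    """Constants for cpm -> receptor-density conversions.

    counting_efficiency : fraction of decays registered by the counter.
    specific_activity_ci_per_mmol : tritiated-ligand specific activity;
        the default is the midpoint of the supplier's 68-85 Ci/mmol range.
    transfection_efficiency : fraction of cells expressing receptor.
    protein_per_cell_ng : total cellular protein per cell, back-computed
        from the printed 335 fmol/mg <-> 26,200 receptors/cell pair.
    cell_volume_pl : assumed cell volume used for the nM conversion.
    """

    counting_efficiency: float = 0.43
    specific_activity_ci_per_mmol: float = 76.5
    transfection_efficiency: float = 0.20
    protein_per_cell_ng: float = 0.13
    cell_volume_pl: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.counting_efficiency <= 1.0:
            raise ValueError("counting_efficiency must be in (0, 1]")
        if self.specific_activity_ci_per_mmol <= 0:
            raise ValueError("specific_activity must be positive")
        if not 0.0 < self.transfection_efficiency <= 1.0:
            raise ValueError("transfection_efficiency must be in (0, 1]")
        if self.protein_per_cell_ng <= 0 or self.cell_volume_pl <= 0:
            raise ValueError("protein_per_cell and cell_volume must be positive")

    @property
    def cpm_per_fmol(self) -> float:
        dpm_per_fmol = self.specific_activity_ci_per_mmol * DPM_PER_CI * 1e-12
        return self.counting_efficiency * dpm_per_fmol


def cpm_to_fmol_per_mg(
    bmax_cpm_per_mg: float, constants: ConversionConstants | None = None
) -> float:
    """Convert a Bmax in cpm/mg protein to fmol receptor/mg protein."""
    constants = constants or ConversionConstants()
    if bmax_cpm_per_mg < 0:
        raise ValueError("cpm must be non-negative")
    return bmax_cpm_per_mg / constants.cpm_per_fmol


def transfection_correction(bulk_conc_fmol_per_mg: float, efficiency: float = 0.20) -> float:
    """Rescale a bulk receptor density to the transfected subpopulation.

    With only a fraction ``efficiency`` of cells expressing receptor, the
    density in expressing cells is the bulk density divided by that fraction
    (e.g. 67.0 fmol/mg at 20% efficiency -> 335 fmol/mg).
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    return bulk_conc_fmol_per_mg / efficiency


def gr_per_cell(
    conc_fmol_per_mg: float, protein_per_cell_ng: float = 0.13
) -> float:
    """Receptors per cell from a density in fmol/mg protein."""
    if conc_fmol_per_mg < 0 or protein_per_cell_ng <= 0:
        raise ValueError("inputs must be positive (conc may be 0)")
    fmol_per_cell = conc_fmol_per_mg * protein_per_cell_ng * 1e-6  # ng -> mg
    return fmol_per_cell * 1e-15 * AVOGADRO


def fmol_per_mg_to_nm(
    conc_fmol_per_mg: float, constants: ConversionConstants | None = None
) -> float:
    """Intracellular receptor concentration in nM.

    Uses protein mass per cell and an assumed cell volume; both are explicit
    assumptions (configurable on :class:`ConversionConstants`).
    """
    constants = constants or ConversionConstants()
    if conc_fmol_per_mg < 0:
        raise ValueError("concentration must be non-negative")
    fmol_per_cell = conc_fmol_per_mg * constants.protein_per_cell_ng * 1e-6
    mol_per_cell = fmol_per_cell * 1e-15
    molar = mol_per_cell / (constants.cell_volume_pl * 1e-12)
    return molar * 1e9
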