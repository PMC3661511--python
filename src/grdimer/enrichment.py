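"""Normalization arithmetic for co-immunoprecipitation densitometry and
ChIP-qPCR promoter-loading data.

Co-IP: the pulled-down (GFP-tagged) receptor band is normalized to the bait
(Flag-tagged) band, then expressed relative to a stated reference condition
(set to 100%).  ChIP: pulled-down promoter DNA is normalized to input DNA
and expressed relative to the no-receptor vehicle baseline; fold recruitment
is the agonist/vehicle ratio within a transfection group.  All four
operations are ratios of like-units quantities and therefore invariant to
common rescaling of the raw band or qPCR values.
"""

from __future__ import annotations

import numpy as np


def coip_normalize(gfp_band, flag_band):
    """Pull-down band normalized to bait band (dimensionless)."""
    gfp = np.asarray(gfp_band, dtype=float)
    flag = np.asarray(flag_band, dtype=float)
    if np.any(gfp < 0):
        raise ValueError("band intensities must be non-negative")
    if np.any(flag <= 0):
        raise ValueError("bait (Flag) band must be positive for normalization")
    return gfp / flag


def coip_relative_to_reference(values, reference: float):
    """Express normalized pull-down values as percent of a reference (=100)."""
    v = np.asarray(values, dtype=float)
    if reference <= 0:
        raise ValueError("reference value must be positive")
    if np.any(v < 0):
        raise ValueError("values must be non-negative")
    return 100.0 * v / reference


def chip_enrichment(pulldown_qpcr, input_qpcr, baseline: float):
    """Input-normalized ChIP signal relative to the no-receptor vehicle.

    ``baseline`` is the input-normalized pulldown of the baseline condition.
    """
    pull = np.asarray(pulldown_qpcr, dtype=float)
    inp = np.asarray(input_qpcr, dtype=float)
    if np.any(inp <= 0):
        raise ValueError("input qPCR abundance must be positive")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return (pull / inp) / baseline


def chip_fold_recruitment(agonist_value, vehicle_value):
    """Agonist-induced fold recruitment over vehicle, within one group."""
    a = np.asarray(agonist_value, dtype=float)
    v = np.asarray(vehicle_value, dtype=float)
    if np.any(v <= 0):
        raise ValueError("vehicle value must be positive")
    if np.any(a < 0):
        raise ValueError("agonist value must be non-negative")
    return a / v
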