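"""Conversions between mRNA half-lives, degradation rate constants,
copy numbers and synthesis rates.

First-order decay gives k = ln(2)/t_half. Metabolic-labeling experiments
observe loss of mRNA per cell that includes dilution by cell growth, so
the observed rate is k_deg + ln(2)/T_doubling; subtracting the dilution
term isolates true degradation. Copy numbers per cell are estimated from
TPM assuming a fixed total mRNA pool per cell (~60,000 molecules in
exponentially growing yeast), and synthesis rates follow from the
steady-state balance: synthesis = steady-state copies x k_deg.
"""

from __future__ import annotations

import logging
import math

import numpy as np

__all__ = [
    "LN2",
    "DEFAULT_MRNA_PER_CELL",
    "rate_from_halflife",
    "halflife_from_rate",
    "correct_for_dilution",
    "copies_from_tpm",
    "protein_per_mrna",
    "synthesis_rate",
]

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: assumed total mRNA molecules per yeast cell for TPM -> copies conversion
DEFAULT_MRNA_PER_CELL = 60_000


def rate_from_halflife(half_life):
    """Degradation rate constant (min^-1) from half-life (min): k = ln2/t."""
    half_life = np.asarray(half_life, dtype=float)
    if np.any(half_life[~np.isnan(half_life)] <= 0):
        raise ValueError("half-life must be positive")
    out = LN2 / half_life
    return float(out) if out.ndim == 0 else out


def halflife_from_rate(k):
    """Half-life (min) from degradation rate constant (min^-1): t = ln2/k."""
    k = np.asarray(k, dtype=float)
    if np.any(k[~np.isnan(k)] <= 0):
        raise ValueError("rate constant must be positive")
    out = LN2 / k
    return float(out) if out.ndim == 0 else out


def correct_for_dilution(k_obs, doubling_time: float):
    """Subtract the growth-dilution rate ln(2)/T_doubling from observed rates.

    Corrected rates that come out non-positive are non-physical (the
    observed loss is no faster than dilution alone); they are set to NaN
    and counted in a warning rather than raised, so table assembly stays
    robust.
    """
    if doubling_time <= 0:
        raise ValueError("doubling time must be positive")
    k_obs = np.asarray(k_obs, dtype=float)
    if np.any(k_obs[~np.isnan(k_obs)] <= 0):
        raise ValueError("observed rate must be positive")
    k_deg = k_obs - LN2 / doubling_time
    nonphysical = k_deg <= 0
    n_bad = int(np.count_nonzero(nonphysical & ~np.isnan(k_obs)))
    if n_bad:
        logger.warning(
            "dilution correction produced %d non-physical (<= 0) rates; set to NaN",
            n_bad,
        )
    k_deg = np.where(nonphysical, np.nan, k_deg)
    return float(k_deg) if k_deg.ndim == 0 else k_deg


def copies_from_tpm(tpm, cell_total: float = DEFAULT_MRNA_PER_CELL):
    """Estimated mRNA molecules per cell from TPM.

    TPM/1e6 is the transcript's fraction of the cellular mRNA pool, scaled
    by the assumed total pool size.
    """
    tpm = np.asarray(tpm, dtype=float)
    if np.any(tpm[~np.isnan(tpm)] < 0):
        raise ValueError("TPM must be non-negative")
    out = tpm / 1e6 * cell_total
    return float(out) if out.ndim == 0 else out


def protein_per_mrna(protein_per_cell, copies_per_cell):
    """Proteins produced per mRNA: protein/cell divided by mRNA copies/cell.

    Zero copy numbers give NaN (reported via warning), not an error.
    """
    protein = np.asarray(protein_per_cell, dtype=float)
    copies = np.asarray(copies_per_cell, dtype=float)
    zero = copies == 0
    n_zero = int(np.count_nonzero(zero))
    if n_zero:
        logger.warning("%d genes have zero mRNA copies; protein/mRNA set to NaN", n_zero)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, np.nan, protein / np.where(zero, np.nan, copies))
    return float(out) if out.ndim == 0 else out


def synthesis_rate(steady_state_copies, k_deg):
    """Synthesis rate (molecules/min) from the steady-state balance.

    At steady state, synthesis = degradation flux = copies x k_deg.
    """
    copies = np.asarray(steady_state_copies, dtype=float)
    k = np.asarray(k_deg, dtype=float)
    if np.any(copies[~np.isnan(copies)] <= 0) or np.any(k[~np.isnan(k)] <= 0):
        raise ValueError("steady-state copies and rate must be positive")
    out = copies * k
    return float(out) if out.ndim == 0 else out
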