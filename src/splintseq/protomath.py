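"""Deterministic bench arithmetic for the library-prep protocol.

Three calculators:

* master-mix tables -- per-well volumes scaled by the reaction count and a
  1.1x pipetting-safety factor, plus final in-well concentrations
  (stock × volume / total well volume, unit preserved);
* qPCR cycle selection -- the test qPCR runs on a 16-fold dilution of the
  library, so the production PCR uses onset_cycle − log2(dilution) cycles
  (subtract 4 for the default 1/16 input); an alternative rule picks a
  fixed offset of 3 cycles before exponential growth;
* molar dilution -- converting ng/μl and mean fragment length into the
  volume holding a target fmol amount for sequencer loading, using dsDNA
  constants 617.96 g/mol per bp plus 36.04 g/mol for the ends.

Well totals are always explicit inputs: several published mix tables imply
mutually inconsistent totals, so nothing is inferred.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

MW_PER_BP = 617.96  # g/mol per dsDNA base pair
MW_ENDS = 36.04  # g/mol, hydroxyl/phosphate ends

#: Typical production-PCR cycle range for this protocol.
TYPICAL_CYCLE_RANGE = (15, 29)


@dataclass(frozen=True)
class MixComponent:
    name: str
    stock_concentration: float
    unit: str  # μM, mM, U/μl, M, x, μg/ml ...
    volume_ul: float

    def __post_init__(self):
        if self.volume_ul < 0:
            raise ValueError("volume must be >= 0")
        if self.stock_concentration <= 0:
            raise ValueError("stock concentration must be > 0")


@dataclass(frozen=True)
class CyclePlan:
    qpcr_onset_cycle: float
    dilution_factor: float
    final_cycles: int


def final_concentration(component: MixComponent, total_well_volume_ul: float) -> float:
    """In-well concentration: stock × volume / total, unit preserved.

    Values are exact; round only for display (2 decimals).
    """
    if total_well_volume_ul <= 0:
        raise ValueError("total well volume must be > 0")
    return component.stock_concentration * component.volume_ul / total_well_volume_ul


def mix_table(
    components: list[MixComponent], n_reactions: int, scale: float = 1.1
) -> pd.DataFrame:
    """Master-mix volumes: per-well and total (× n_reactions × scale)."""
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    rows = [
        {
            "component": c.name,
            "per_well_ul": c.volume_ul,
            "total_ul": c.volume_ul * n_reactions * scale,
        }
        for c in components
    ]
    df = pd.DataFrame(rows)
    total = {
        "component": "TOTAL",
        "per_well_ul": df["per_well_ul"].sum(),
        "total_ul": df["total_ul"].sum(),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def pcr_cycles(onset_cycle: float, dilution_factor: float = 16) -> CyclePlan:
    """Production-PCR cycles from the qPCR onset on diluted input.

    final = onset − log2(dilution_factor); with the default 1/16 qPCR input
    this subtracts 4.  Non-power-of-two dilutions give a non-integer offset
    which is rounded with a warning; a final count outside the typical
    15-29 range also warns.
    """
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be > 0")
    offset = math.log2(dilution_factor)
    raw = onset_cycle - offset
    if raw < 1:
        raise ValueError(
            f"onset cycle {onset_cycle} too low for a {dilution_factor}x dilution"
        )
    if abs(offset - round(offset)) > 1e-9:
        warnings.warn(
            f"dilution {dilution_factor} is not a power of two; "
            f"cycle offset {offset:.2f} rounded", stacklevel=2
        )
    final = int(round(raw))
    lo, hi = TYPICAL_CYCLE_RANGE
    if not lo <= final <= hi:
        warnings.warn(
            f"final cycle count {final} outside typical range {lo}-{hi}",
            stacklevel=2,
        )
    return CyclePlan(onset_cycle, dilution_factor, final)


def pcr_cycles_pre_onset(onset_cycle: float, offset: int = 3) -> CyclePlan:
    """Alternative rule: a fixed number of cycles before exponential growth.

    Kept as a second named rule alongside :func:`pcr_cycles`; the two are
    not reconciled and neither is canonical.
    """
    raw = onset_cycle - offset
    if raw < 1:
        raise ValueError("onset cycle too low for the requested offset")
    return CyclePlan(onset_cycle, 1.0, int(round(raw)))


def dsdna_molarity_fmol_per_ul(concentration_ng_per_ul: float, mean_length_bp: float) -> float:
    """Molar concentration of a dsDNA library in fmol/μl."""
    if concentration_ng_per_ul <= 0 or mean_length_bp <= 0:
        raise ValueError("concentration and length must be > 0")
    mw = mean_length_bp * MW_PER_BP + MW_ENDS  # g/mol
    # ng/μl = 1e-9 g / 1e-6 L = 1e-3 g/L; ×1e15 fmol/mol; ×1e-6 L/μl
    return concentration_ng_per_ul * 1e6 / mw


def fmol_dilution(
    concentration_ng_per_ul: float, mean_length_bp: float, target_fmol: float
) -> float:
    """Volume (μl) of library containing ``target_fmol`` of molecules."""
    if target_fmol < 0:
        raise ValueError("target_fmol must be >= 0")
    if target_fmol == 0:
        return 0.0
    return target_fmol / dsdna_molarity_fmol_per_ul(
        concentration_ng_per_ul, mean_length_bp
    )
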