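"""Phage-display selection analytics: titers, enrichment, ELISA specificity.

Panning rounds are characterized by an enrichment ratio (phage eluted from
the target sorting over phage eluted from the negative control), phage
stocks are quantified from absorbance at 268 nm or from colony counts, and
phage-ELISA plates are reduced to background-subtracted, per-target signals
with a specificity index for the primary target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: phage per mL at OD268 = 1.0 for filamentous phage stocks
OD268_PHAGE_PER_ML = 5e12

#: the two printed round-stringency schedules (target concentration in nM
#: per round); both ship as presets because the source protocol reports both
STRINGENCY_PRESETS = {
    "results-schedule": (100.0, 50.0, 25.0),
    "methods-schedule": (100.0, 20.0, 4.0),
}


@dataclass(frozen=True)
class PanningRound:
    """One biopanning round with its eluted titers."""

    round_index: int
    target_concentration_nM: float
    eluted_target_titer: float  # phage/mL
    eluted_control_titer: float  # phage/mL

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        if self.eluted_target_titer < 0 or self.eluted_control_titer < 0:
            raise ValueError("titers must be non-negative")


@dataclass(frozen=True)
class Enrichment:
    """Enrichment ratio; ``unbounded`` marks a zero-control sentinel result."""

    value: float
    unbounded: bool = False


def titer_from_od268(od: float, dilution: float = 1.0) -> float:
    """Phage per mL from absorbance at 268 nm (OD 1.0 = 5e12 phage/mL)."""
    if od < 0 or dilution < 1:
        raise ValueError("od must be >= 0 and dilution >= 1")
    return od * OD268_PHAGE_PER_ML * dilution


def titer_from_colonies(colonies: int, dilution: float, plated_volume_ml: float) -> float:
    """Colony-forming units per mL from a plated serial dilution."""
    if plated_volume_ml <= 0:
        raise ValueError("plated volume must be positive")
    if colonies < 0 or dilution < 1:
        raise ValueError("colonies must be >= 0 and dilution >= 1")
    return colonies * dilution / plated_volume_ml


def enrichment_ratio(rnd: PanningRound) -> Enrichment:
    """Target-elution titer over control-elution titer for one round."""
    if rnd.eluted_control_titer == 0:
        return Enrichment(value=math.inf, unbounded=True)
    return Enrichment(value=rnd.eluted_target_titer / rnd.eluted_control_titer)


# ---------------------------------------------------------------------------
# Phage-ELISA
# ---------------------------------------------------------------------------

@dataclass
class ElisaPlate:
    """OD450 plate: clones x targets, with per-target blank wells."""

    od450: pd.DataFrame  # index: clone ids; columns: target names
    blanks: pd.DataFrame  # index: blank replicate; columns: target names

    def __post_init__(self) -> None:
        if (self.od450.values < 0).any() or (self.blanks.values < 0).any():
            raise ValueError("OD values must be non-negative")
        missing = [t for t in self.od450.columns if t not in self.blanks.columns
                   or self.blanks[t].dropna().empty]
        if missing:
            raise ValueError(f"targets without blank wells: {missing}")

    @classmethod
    def from_csv(cls, path) -> "ElisaPlate":
        """Plate CSV: rows = clones, columns = targets, BLANK* rows reserved."""
        df = pd.read_csv(path, index_col=0)
        is_blank = df.index.astype(str).str.upper().str.startswith("BLANK")
        return cls(od450=df.loc[~is_blank], blanks=df.loc[is_blank])


@dataclass(frozen=True)
class ElisaResult:
    clone: str
    signals: dict[str, float]  # blank-subtracted, clipped at 0
    primary_target: str
    specificity_index: float  # inf when every other target signal is 0
    binder_call: bool


def elisa_specificity(
    plate: ElisaPlate,
    clone: str,
    primary_target: str,
    k_sigma: float = 3.0,
) -> ElisaResult:
    """Background-subtracted signals and specificity index for one clone.

    Per target, the mean blank OD is subtracted and negatives clip to 0.
    The specificity index is signal(primary) / max(signal(other targets)),
    infinite when all other signals are zero.  The clone is called a binder
    when its primary signal exceeds ``k_sigma`` blank standard deviations.
    """
    if primary_target not in plate.od450.columns:
        raise ValueError(f"primary target {primary_target!r} not on plate")
    blank_mean = plate.blanks.mean(axis=0)
    signals = {
        t: max(0.0, float(plate.od450.loc[clone, t] - blank_mean[t]))
        for t in plate.od450.columns
    }
    others = [signals[t] for t in signals if t != primary_target]
    primary = signals[primary_target]
    if others and max(others) > 0:
        index = primary / max(others)
    else:
        index = math.inf
    blank_sd = float(plate.blanks[primary_target].std(ddof=1))
    if math.isnan(blank_sd):  # single blank well
        blank_sd = 0.0
    return ElisaResult(
        clone=clone, signals=signals, primary_target=primary_target,
        specificity_index=index, binder_call=primary > k_sigma * blank_sd,
    )


def read_round_table(path) -> list[PanningRound]:
    """Round CSV: round, conc_nM, target_count, control_count, dilution, volume_ml."""
    df = pd.read_csv(path)
    rounds = []
    for _, row in df.iterrows():
        rounds.append(PanningRound(
            round_index=int(row["round"]),
            target_concentration_nM=float(row["conc_nM"]),
            eluted_target_titer=titer_from_colonies(
                int(row["target_count"]), float(row["dilution"]), float(row["volume_ml"])),
            eluted_control_titer=titer_from_colonies(
                int(row["control_count"]), float(row["dilution"]), float(row["volume_ml"])),
        ))
    return rounds
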