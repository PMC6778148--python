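"""Chemical-shift-perturbation epitope mapping from amide HSQC shift tables.

Binding epitopes are read out residue-by-residue from the movement of
backbone amide crosspeaks between the free and bound 15N-HSQC spectra.
The combined 1H/15N perturbation is
``sqrt(0.14 * d15N**2 + d1HN**2)`` (the 15N term down-weighted for the
wider 15N ppm scale), residues classify as strong (> 0.3 ppm), moderate
(0.15-0.3 ppm) or background, and peaks that broaden out or lack data
carry their own classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

STRONG_DEFAULT = 0.3
MODERATE_DEFAULT = 0.15

CLASSES = ("strong", "moderate", "background", "broadened", "no-data")


class ReconciliationError(ValueError):
    """Free/bound tables disagree on residue numbering."""


def combined_csp(d15n: float, d1hn: float, scale_inside: bool = False) -> float:
    """Combined amide chemical-shift perturbation in ppm.

    ``sqrt(0.14 * d15N^2 + d1HN^2)`` by default (the weight multiplies the
    squared 15N shift); ``scale_inside`` switches to the common alternative
    ``sqrt((0.14 * d15N)^2 + d1HN^2)``.  Symmetric in the sign of both
    inputs.
    """
    if not (math.isfinite(d15n) and math.isfinite(d1hn)):
        raise ValueError("shift differences must be finite")
    if scale_inside:
        return math.sqrt((0.14 * d15n) ** 2 + d1hn ** 2)
    return math.sqrt(0.14 * d15n ** 2 + d1hn ** 2)


def read_shift_table(path) -> pd.DataFrame:
    """Shift-table CSV: residue, resname, h_ppm, n_ppm [, broadened, missing].

    Flag columns are optional and parsed as booleans (empty = False).
    """
    df = pd.read_csv(path)
    for col in ("broadened", "missing"):
        if col not in df.columns:
            df[col] = False
        else:
            df[col] = df[col].fillna(False).astype(bool)
    if df["residue"].duplicated().any():
        dup = df.loc[df["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"duplicate residue rows: {dup}")
    return df


@dataclass
class EpitopeMap:
    """Per-residue combined perturbation and threshold class."""

    table: pd.DataFrame  # columns: residue, resname, delta_ppm, cls
    thresholds: tuple[float, float]

    def residues_in(self, *classes: str) -> set[int]:
        mask = self.table["cls"].isin(classes)
        return set(self.table.loc[mask, "residue"].astype(int))

    @property
    def epitope(self) -> set[int]:
        """Residues above the moderate threshold (strong or moderate)."""
        return self.residues_in("strong", "moderate")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def viewer_selection(self, *classes: str) -> str:
        """Residue-list fragment for structure-viewer colouring (plain text)."""
        if not classes:
            classes = ("strong", "moderate")
        resi = sorted(self.residues_in(*classes))
        return "+".join(str(r) for r in resi)


def epitope_map(
    free: pd.DataFrame,
    bound: pd.DataFrame,
    thresholds: tuple[float, float] = (STRONG_DEFAULT, MODERATE_DEFAULT),
    scale_inside: bool = False,
) -> EpitopeMap:
    """Classify every residue by its combined shift perturbation.

    Classes: strong when delta > thresholds[0]; moderate when
    thresholds[1] < delta <= thresholds[0]; background otherwise.  A
    residue broadened in the bound state is classed ``broadened``
    regardless of its delta; residues flagged missing/ambiguous in either
    state carry ``no-data``.  The two tables must agree on residue
    numbering.
    """
    hi, lo = thresholds
    if hi < lo:
        raise ValueError("thresholds must be (strong, moderate) with strong >= moderate")
    fr = free.set_index("residue", drop=False).sort_index()
    bo = bound.set_index("residue", drop=False).sort_index()
    offenders = sorted(set(fr.index) ^ set(bo.index))
    if offenders:
        raise ReconciliationError(f"residues present in only one table: {offenders}")

    rows = []
    for res in fr.index:
        f, b = fr.loc[res], bo.loc[res]
        if bool(f.get("missing", False)) or bool(b.get("missing", False)):
            delta, cls = float("nan"), "no-data"
        elif bool(b.get("broadened", False)):
            delta, cls = float("nan"), "broadened"
        else:
            delta = combined_csp(b["n_ppm"] - f["n_ppm"], b["h_ppm"] - f["h_ppm"],
                                 scale_inside=scale_inside)
            cls = "strong" if delta > hi else ("moderate" if delta > lo else "background")
        rows.append({"residue": int(res), "resname": f.get("resname", ""),
                     "delta_ppm": delta, "cls": cls})
    return EpitopeMap(table=pd.DataFrame(rows), thresholds=(hi, lo))


@dataclass(frozen=True)
class EpitopeOverlap:
    shared_strong: set[int]
    unique_strong_a: set[int]
    unique_strong_b: set[int]
    jaccard: float  # on strong + moderate sets


def compare_epitopes(map_a: EpitopeMap, map_b: EpitopeMap) -> EpitopeOverlap:
    """Set overlap of two epitope maps defined over the same residues."""
    univ_a = set(map_a.table["residue"].astype(int))
    univ_b = set(map_b.table["residue"].astype(int))
    if univ_a != univ_b:
        raise ReconciliationError("epitope maps cover different residue universes")
    sa, sb = map_a.residues_in("strong"), map_b.residues_in("strong")
    ea, eb = map_a.epitope, map_b.epitope
    union = ea | eb
    jac = len(ea & eb) / len(union) if union else 1.0
    return EpitopeOverlap(
        shared_strong=sa & sb, unique_strong_a=sa - sb, unique_strong_b=sb - sa,
        jaccard=jac,
    )
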