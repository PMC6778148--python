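"""Degenerate-codon library design: expansion, diversity math, oligo sets.

Combinatorial loop libraries on the 10FN3 scaffold are built from NNK
degenerate codons (N = any base, K = G/T), which cover all 20 amino acids
with a single amber (TAG) stop out of 32 codons.  This module provides the
codon-level probability math, the per-length mutagenic oligo specifications,
exact theoretical diversity counts, stop-codon statistics and a
birthday-model lower bound on realized library size from colony sequencing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

from Bio.Seq import Seq

from fn3kit.scaffold import ScaffoldTemplate

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}
AMBER = "TAG"


@dataclass(frozen=True)
class DegenerateCodon:
    """A 3-letter IUPAC DNA codon with equal per-base probabilities."""

    iupac: str

    def __post_init__(self) -> None:
        if len(self.iupac) != 3 or any(b not in IUPAC_DNA for b in self.iupac.upper()):
            raise ValueError(f"not a 3-letter IUPAC DNA codon: {self.iupac!r}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    @property
    def expansion(self) -> list[tuple[str, Fraction]]:
        return expand_degenerate_codon(self)

    @property
    def n_codons(self) -> int:
        return math.prod(len(IUPAC_DNA[b]) for b in self.iupac)


NNK = DegenerateCodon("NNK")


def expand_degenerate_codon(codon: DegenerateCodon | str) -> list[tuple[str, Fraction]]:
    """Enumerate the concrete codons of a degenerate codon with probabilities.

    Each IUPAC position contributes its allowed bases with equal weight, so
    every concrete codon carries probability 1 / (product of degeneracies).
    """
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    p = Fraction(1, codon.n_codons)
    return [("".join(bases), p) for bases in product(*(IUPAC_DNA[b] for b in codon.iupac))]


def aa_distribution(
    codon: DegenerateCodon | str, amber_suppression: bool = False
) -> dict[str, Fraction]:
    """Amino-acid (and ``*`` stop) probabilities of a degenerate codon.

    Computed by translating the full expansion with the standard genetic
    code (NCBI table 1).  With ``amber_suppression`` the amber TAG codon is
    counted as glutamine (supE-type readthrough) instead of stop.
    """
    dist: dict[str, Fraction] = {}
    for concrete, p in expand_degenerate_codon(codon):
        if amber_suppression and concrete == AMBER:
            aa = "Q"
        else:
            aa = str(Seq(concrete).translate())
        dist[aa] = dist.get(aa, Fraction(0)) + p
    return dist


@dataclass(frozen=True)
class LoopDesign:
    """Diversification plan for one scaffold loop.

    ``anchor_codon_position`` is the first diversified codon in 1-based
    wild-type 10FN3 numbering; ``length_range`` is the inclusive [min, max]
    range of inserted degenerate codons.
    """

    loop_id: str
    anchor_codon_position: int
    length_range: tuple[int, int]
    codon_scheme: DegenerateCodon = NNK

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or lo > hi:
            raise ValueError(f"invalid length range {self.length_range}")

    @property
    def lengths(self) -> range:
        return range(self.length_range[0], self.length_range[1] + 1)


@dataclass(frozen=True)
class LibraryDesign:
    """Full library plan: scaffold plus a set of non-overlapping loop designs."""

    scaffold: ScaffoldTemplate | None
    loops: tuple[LoopDesign, ...]
    translation_table_id: int = 1

    def __post_init__(self) -> None:
        if not self.loops:
            raise ValueError("library design needs at least one loop")
        if self.scaffold is not None:
            spans = []
            for loop in self.loops:
                region = self.scaffold.loops[loop.loop_id]
                spans.append((region.start_codon, region.start_codon + region.wt_codons))
            spans.sort()
            for (_, end_a), (start_b, _) in zip(spans, spans[1:]):
                if start_b < end_a:
                    raise ValueError("loop regions overlap on the scaffold")

    def to_json(self) -> str:
        return json.dumps(
            {
                "scaffold": self.scaffold.name if self.scaffold else None,
                "translation_table_id": self.translation_table_id,
                "loops": [
                    {
                        "loop_id": lp.loop_id,
                        "anchor_codon_position": lp.anchor_codon_position,
                        "length_range": list(lp.length_range),
                        "codon_scheme": lp.codon_scheme.iupac,
                    }
                    for lp in self.loops
                ],
            },
            indent=2,
        )


def default_library_design(scaffold: ScaffoldTemplate) -> LibraryDesign:
    """BC 5-9 and FG 7-13 NNK codon design at 10FN3 positions 25 and 75."""
    return LibraryDesign(
        scaffold=scaffold,
        loops=(
            LoopDesign("BC", anchor_codon_position=25, length_range=(5, 9)),
            LoopDesign("FG", anchor_codon_position=75, length_range=(7, 13)),
        ),
    )


@dataclass(frozen=True)
class OligoSpec:
    """One mutagenic oligo: fixed 5' flank, L degenerate codons, fixed 3' flank."""

    name: str
    loop_id: str
    n_random_codons: int
    sequence: str  # IUPAC letters preserved in the degenerate stretch


def design_loop_oligos(
    design: LoopDesign, scaffold: ScaffoldTemplate, flank_len: int = 6
) -> list[OligoSpec]:
    """Mutagenic oligo set for one loop: one oligo per loop length.

    Each oligo anneals on ``flank_len`` fixed codons on both sides of the
    variable region and carries L copies of the degenerate codon in the
    scaffold frame, for L over the design's length range.
    """
    region = scaffold.loops[design.loop_id]
    if region.start_codon != design.anchor_codon_position:
        raise ValueError(
            f"design anchors loop {design.loop_id} at codon "
            f"{design.anchor_codon_position} but scaffold places it at {region.start_codon}"
        )
    start, end = scaffold.loop_span(design.loop_id)
    if start - 3 * flank_len < 0 or end + 3 * flank_len > len(scaffold.dna):
        raise ValueError("anchor/flank outside scaffold")
    five = scaffold.dna[start - 3 * flank_len: start]
    three = scaffold.dna[end: end + 3 * flank_len]
    return [
        OligoSpec(
            name=f"{design.loop_id}-{n}xNNK" if design.codon_scheme.iupac == "NNK"
            else f"{design.loop_id}-{n}x{design.codon_scheme.iupac}",
            loop_id=design.loop_id,
            n_random_codons=n,
            sequence=five + design.codon_scheme.iupac * n + three,
        )
        for n in design.lengths
    ]


def oligos_to_fasta(oligos: list[OligoSpec]) -> str:
    return "".join(f">{o.name}\n{o.sequence}\n" for o in oligos)


def _per_codon_variants(codon: DegenerateCodon, level: str, stop_free: bool) -> int:
    if level == "dna":
        if stop_free:
            return sum(1 for c, _ in expand_degenerate_codon(codon) if c not in STOP_CODONS)
        return codon.n_codons
    if level == "protein":
        dist = aa_distribution(codon)
        residues = set(dist) - ({"*"} if stop_free else set())
        return len(residues)
    raise ValueError(f"unknown level {level!r}")


def theoretical_diversity(
    design: LibraryDesign, level: str = "dna", stop_free: bool = False
) -> tuple[int, float]:
    """Exact theoretical library diversity as a big integer, with log10.

    Per loop, variant counts are summed over the length range (one oligo per
    length, lengths combined equimolar); loops multiply.  At the DNA level a
    length-L stretch of one degenerate codon contributes (expansion size)^L
    variants; at the protein level (distinct residues)^L, excluding stop
    codons when ``stop_free``.
    """
    total = 1
    for loop in design.loops:
        per_codon = _per_codon_variants(loop.codon_scheme, level, stop_free)
        total *= sum(per_codon ** n for n in loop.lengths)
    return total, math.log10(total)


def stop_free_fraction(
    design: LibraryDesign,
    amber_suppression: bool = False,
    fixed_lengths: dict[str, int] | None = None,
) -> float:
    """Probability that a random library member carries no in-loop stop codon.

    Each diversified codon independently avoids a stop with probability
    (1 - per-codon stop probability); length combinations are weighted
    equally (the per-length oligos are pooled equimolar).  ``fixed_lengths``
    restricts each named loop to a single length.
    """
    frac = Fraction(1)
    for loop in design.loops:
        dist = aa_distribution(loop.codon_scheme, amber_suppression=amber_suppression)
        p_ok = 1 - dist.get("*", Fraction(0))
        if fixed_lengths and loop.loop_id in fixed_lengths:
            frac *= p_ok ** fixed_lengths[loop.loop_id]
        else:
            lengths = list(loop.lengths)
            frac *= Fraction(sum(p_ok ** n for n in lengths), len(lengths))
    return float(frac)


def _log_p_no_collision(n: int, diversity: int) -> float:
    """log P(all n draws distinct) under uniform sampling from ``diversity`` clones."""
    if diversity < n:
        return -math.inf
    return sum(math.log1p(-i / diversity) for i in range(n))


def collision_diversity_bound(
    n_sampled: int, n_collisions: int, confidence: float = 0.95
) -> int:
    """Birthday-model lower confidence bound on the number of distinct clones.

    Given ``n_sampled`` uniform draws from a library of unknown size D with
    ``n_collisions`` observed collisions (draws minus distinct sequences),
    returns the smallest D for which observing at most that many collisions
    has probability >= 1 - confidence.  Zero collisions use the exact
    product formula P(no collision) = prod_i (1 - i/D); positive counts use
    the Poisson approximation with mean C(n,2)/D.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if n_collisions > n_sampled:
        raise ValueError("n_collisions cannot exceed n_sampled")
    if n_collisions >= n_sampled - 1:
        return 1
    alpha = 1.0 - confidence

    if n_collisions == 0:
        def p_ok(d: int) -> float:
            return math.exp(_log_p_no_collision(n_sampled, d))
    else:
        from scipy.stats import poisson

        pairs = n_sampled * (n_sampled - 1) // 2

        def p_ok(d: int) -> float:
            return float(poisson.cdf(n_collisions, pairs / d))

    lo, hi = n_sampled - n_collisions, n_sampled - n_collisions
    while p_ok(hi) < alpha:
        hi *= 2
    while hi - lo > 0:
        mid = (lo + hi) // 2
        if p_ok(mid) >= alpha:
            hi = mid
        else:
            lo = mid + 1
    return hi
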