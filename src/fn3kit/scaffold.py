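"""Display-cassette scaffold template: reference sequence, loop anchors, sites.

A :class:`ScaffoldTemplate` describes the fixed part of the phagemid display
cassette: the reference DNA, its translation, the codon coordinates of the
diversified loops (BC and FG in 10FN3), and the restriction sites whose
presence a sequenced clone must retain to have been cloned correctly.

Codon positions at the user interface follow the 1-based wild-type 10FN3
numbering (the convention of PDB entry 1FNA); nucleotide indices internally
are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from Bio.Seq import Seq

#: wild-type 10FN3 domain, residues 1-94 in 1FNA numbering
FN3_WT_PROTEIN = (
    "VSDVPRDLEVVAATPTSLLISWDAPAVTVRYYRITYGETGGNSPVQEFTVPGSKSTATIS"
    "GLKPGVDYTITVYAVTGRGDSPASSKPISINYRT"
)

#: one fixed codon per amino acid, chosen so that no restriction site of the
#: default cassette can arise inside the coding region
_BACKTRANSLATION = {
    "A": "GCT", "R": "CGT", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCG",
    "S": "TCT", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTT",
}

DEFAULT_REQUIRED_SITES = [
    ("HindIII", "AAGCTT"),
    ("BamHI", "GGATCC"),
    ("NotI", "GCGGCCGC"),
    ("KpnI", "GGTACC"),
]


@dataclass(frozen=True)
class LoopRegion:
    """Variable region of one loop, in 10FN3 codon coordinates.

    ``start_codon`` is the first diversified codon (1-based 10FN3 numbering)
    and ``wt_codons`` the number of wild-type codons it replaces.
    """

    loop_id: str
    start_codon: int
    wt_codons: int


@dataclass
class ScaffoldTemplate:
    """Reference DNA/protein of the display cassette with loop anchors."""

    name: str
    dna: str
    protein: str
    loops: dict[str, LoopRegion]
    required_sites: list[tuple[str, str]]
    frame_offset: int  # 0-based nt index of the initiator ATG

    def __post_init__(self) -> None:
        self.dna = self.dna.upper()
        coding = self.dna[self.frame_offset:]
        coding = coding[: 3 * (len(coding) // 3)]
        translated = str(Seq(coding).translate())
        translated = translated.split("*", 1)[0]
        if translated != self.protein:
            raise ValueError("translation of dna at frame_offset does not match protein")
        for loop_id, region in self.loops.items():
            for flank in (self.five_flank(loop_id), self.three_flank(loop_id)):
                if self.dna.count(flank) != 1:
                    raise ValueError(f"anchor of loop {loop_id} not unique in scaffold dna")

    # -- coordinate helpers -------------------------------------------------
    def codon_nt(self, fn3_codon: int) -> int:
        """0-based nt index of a 1-based 10FN3 codon (Met occupies codon 0)."""
        return self.frame_offset + 3 * fn3_codon

    def loop_span(self, loop_id: str) -> tuple[int, int]:
        """Half-open nt span of the variable region of ``loop_id``."""
        region = self.loops[loop_id]
        start = self.codon_nt(region.start_codon)
        return start, start + 3 * region.wt_codons

    def five_flank(self, loop_id: str, n_nt: int = 18) -> str:
        start, _ = self.loop_span(loop_id)
        return self.dna[start - n_nt: start]

    def three_flank(self, loop_id: str, n_nt: int = 18) -> str:
        _, end = self.loop_span(loop_id)
        return self.dna[end: end + n_nt]

    def with_loops(self, loop_dna: dict[str, str]) -> str:
        """Cassette DNA with each variable region replaced by the given insert."""
        spans = sorted(
            ((self.loop_span(lid), lid) for lid in self.loops), key=lambda x: x[0][0]
        )
        out, prev = [], 0
        for (start, end), lid in spans:
            out.append(self.dna[prev:start])
            out.append(loop_dna.get(lid, self.dna[start:end]))
            prev = end
        out.append(self.dna[prev:])
        return "".join(out)

    # -- (de)serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "dna": self.dna,
                "protein": self.protein,
                "frame_offset": self.frame_offset,
                "loops": {
                    lid: {"start_codon": r.start_codon, "wt_codons": r.wt_codons}
                    for lid, r in self.loops.items()
                },
                "required_sites": list(map(list, self.required_sites)),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaffoldTemplate":
        obj = json.loads(text)
        return cls(
            name=obj["name"],
            dna=obj["dna"],
            protein=obj["protein"],
            loops={
                lid: LoopRegion(lid, d["start_codon"], d["wt_codons"])
                for lid, d in obj["loops"].items()
            },
            required_sites=[tuple(s) for s in obj["required_sites"]],
            frame_offset=obj["frame_offset"],
        )


def default_scaffold() -> ScaffoldTemplate:
    """Synthetic default display cassette for a BC/FG-diversified 10FN3 phagemid.

    This is a synthetic construct assembled in code, not a deposited vector
    sequence: the wild-type 10FN3 protein is back-translated with one fixed
    codon per residue and framed by a HindIII site and ribosome-binding
    spacer on the 5' side, and KpnI (Gly-Thr) plus NotI (Ala-Ala-Ala) sites,
    a stop codon and a BamHI site on the 3' side.  BC-loop codons 25-29 and
    FG-loop codons 75-81 (1FNA numbering) are the diversified regions.
    """
    fn3_codons = "".join(_BACKTRANSLATION[aa] for aa in FN3_WT_PROTEIN)
    pad5 = "GCTGACTGACTG"
    rbs = "AGGA"
    tail = "GGTACC" + "GCGGCCGCA" + "TAA"
    pad3 = "TGGCCTCGAGTT"
    dna = pad5 + "AAGCTT" + rbs + "ATG" + fn3_codons + tail + "GGATCC" + pad3
    frame_offset = len(pad5) + 6 + len(rbs)
    protein = "M" + FN3_WT_PROTEIN + "GT" + "AAA"
    return ScaffoldTemplate(
        name="fn3-display-cassette",
        dna=dna,
        protein=protein,
        loops={
            "BC": LoopRegion("BC", start_codon=25, wt_codons=5),
            "FG": LoopRegion("FG", start_codon=75, wt_codons=7),
        },
        required_sites=list(DEFAULT_REQUIRED_SITES),
        frame_offset=frame_offset,
    )
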