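"""Pre-processing of Sanger clone reads: orientation, frame, validity, loops.

Each sequenced colony read is oriented against the scaffold cassette,
assigned a reading frame, translated, and screened: a valid clone must
retain every required restriction site and carry no stop codon (and no
ambiguous base) inside its variable loop regions.  All checks run and
accumulate failure reasons; content problems never raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from fn3kit.scaffold import ScaffoldTemplate

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ReadRecord:
    """One raw sequencing read (A/C/G/T/N alphabet)."""

    read_id: str
    dna: str
    quality: tuple[int, ...] | None = None  # carried but unused by default

    def __post_init__(self) -> None:
        object.__setattr__(self, "dna", self.dna.upper())
        if set(self.dna) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: alphabet outside ACGTN")


@dataclass
class CloneRecord:
    """One colony after orientation/frame resolution and validity screening."""

    read_id: str
    oriented_dna: str
    orientation: str  # "forward" | "reverse" | "unknown"
    frame_offset: int
    protein: str
    loop_peptides: dict[str, tuple[str, str]]  # loop_id -> (dna, peptide)
    status: str  # "valid" | "invalid"
    failure_reasons: list[str] = field(default_factory=list)


def _revcomp(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _scan(read_arr: np.ndarray, kmer: str, max_mm: int) -> tuple[int, int] | None:
    """Best (mismatches, position) of ``kmer`` in the read, or None.

    Ties on mismatch count resolve to the leftmost position.
    """
    k = len(kmer)
    if len(read_arr) < k:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(read_arr, k)
    mismatches = (windows != _encode(kmer)).sum(axis=1)
    pos = int(mismatches.argmin())
    best = int(mismatches[pos])
    if best > max_mm:
        return None
    return best, pos


def _anchor_kmers(scaffold: ScaffoldTemplate, k: int) -> list[tuple[str, int]]:
    """(k-mer, template nt position) for both flanks of every loop."""
    out = []
    for loop_id in scaffold.loops:
        start, end = scaffold.loop_span(loop_id)
        out.append((scaffold.dna[start - k: start], start - k))
        out.append((scaffold.dna[end: end + k], end))
    return out


def orient_and_frame(
    read: ReadRecord,
    scaffold: ScaffoldTemplate,
    max_anchor_mismatch: int = 2,
    anchor_k: int = 18,
) -> tuple[str, int] | None:
    """Resolve strand and reading frame of a read against the scaffold.

    Searches both strands for the fixed loop-flank k-mers allowing up to
    ``max_anchor_mismatch`` substitutions; the strand of the best hit wins
    (ties: fewest mismatches, then leftmost hit, then forward strand).  The
    frame follows from the anchor's codon phase on the template.  When no
    anchor is found, falls back to six-frame protein alignment against the
    scaffold translation.  Returns (orientation, frame_offset) with the
    frame given on the oriented strand, or None for an unalignable read.
    """
    anchors = _anchor_kmers(scaffold, anchor_k)
    best: tuple[int, int, int, str, int] | None = None  # mm, pos, strand_rank, orient, tpos
    for orient, seq in (("forward", read.dna), ("reverse", _revcomp(read.dna))):
        arr = _encode(seq)
        for kmer, tpos in anchors:
            hit = _scan(arr, kmer, max_anchor_mismatch)
            if hit is None:
                continue
            mm, pos = hit
            cand = (mm, pos, 0 if orient == "forward" else 1, orient, tpos)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is not None:
        _, pos, _, orient, tpos = best
        # anchors sit on codon boundaries of the template, so the read frame
        # is the anchor hit position modulo 3, shifted by the template phase
        phase = (tpos - scaffold.frame_offset) % 3
        return orient, (pos - phase) % 3

    return _six_frame_fallback(read, scaffold)


def _six_frame_fallback(
    read: ReadRecord, scaffold: ScaffoldTemplate
) -> tuple[str, int] | None:
    aligner = PairwiseAligner(mode="local", match_score=2, mismatch_score=-1,
                              open_gap_score=-4, extend_gap_score=-1)
    best = None
    for orient, seq in (("forward", read.dna), ("reverse", _revcomp(read.dna))):
        for frame in range(3):
            coding = seq[frame:]
            coding = coding[: 3 * (len(coding) // 3)]
            if len(coding) < 30:
                continue
            pep = str(Seq(coding.replace("N", "A")).translate()).replace("*", "X")
            score = aligner.score(scaffold.protein, pep)
            cand = (score, 0 if orient == "forward" else 1, frame)
            if best is None or (cand[0], -cand[1], -cand[2]) > (best[0], -best[1], -best[2]):
                best = (score, cand[1], frame, orient)
    if best is None or best[0] < 20:  # require ~10 aligned identical residues
        return None
    return best[3], best[2]


def _find_anchor_pair(
    oriented: str, scaffold: ScaffoldTemplate, loop_id: str,
    max_anchor_mismatch: int, anchor_k: int,
) -> tuple[int, int] | None:
    """Half-open span of the variable region of ``loop_id`` within the read."""
    start, end = scaffold.loop_span(loop_id)
    five = scaffold.dna[start - anchor_k: start]
    three = scaffold.dna[end: end + anchor_k]
    arr = _encode(oriented)
    hit5 = _scan(arr, five, max_anchor_mismatch)
    hit3 = _scan(arr, three, max_anchor_mismatch)
    if hit5 is None or hit3 is None:
        return None
    loop_start = hit5[1] + anchor_k
    loop_end = hit3[1]
    if loop_end < loop_start:
        return None
    return loop_start, loop_end


def extract_loops(
    oriented_dna: str,
    scaffold: ScaffoldTemplate,
    max_anchor_mismatch: int = 2,
    anchor_k: int = 18,
) -> dict[str, tuple[str, str]]:
    """Loop DNA and peptide for every scaffold loop of an oriented read.

    The loop is the in-frame stretch strictly between the 5' and 3' fixed
    flanks; variable lengths are supported.  Raises ``LoopExtractionError``
    when an anchor pair is absent, out of order, or off-frame.
    """
    out: dict[str, tuple[str, str]] = {}
    for loop_id in scaffold.loops:
        span = _find_anchor_pair(oriented_dna, scaffold, loop_id, max_anchor_mismatch, anchor_k)
        if span is None:
            raise LoopExtractionError(f"anchors of loop {loop_id} not found or out of order")
        start, end = span
        loop_dna = oriented_dna[start:end]
        if len(loop_dna) % 3 != 0:
            raise LoopExtractionError(f"loop {loop_id} length not a codon multiple")
        pep = str(Seq(loop_dna.replace("N", "A")).translate()) if loop_dna else ""
        if "N" in loop_dna:
            pep = "".join(
                "X" if "N" in loop_dna[3 * i: 3 * i + 3] else aa for i, aa in enumerate(pep)
            )
        out[loop_id] = (loop_dna, pep)
    return out


class LoopExtractionError(ValueError):
    pass


def validate_clone(
    read: ReadRecord,
    scaffold: ScaffoldTemplate,
    max_anchor_mismatch: int = 2,
    anchor_k: int = 18,
    screen_whole_orf: bool = False,
) -> CloneRecord:
    """Full validity screen of one read; content problems become reasons.

    Runs orientation/frame resolution, translation, an exact-match check of
    every required restriction site on the oriented read, and an in-frame
    stop-codon / ambiguous-base screen of each variable loop.  All checks
    run (no short-circuit); ``status`` is valid only with an empty reason
    list.  ``screen_whole_orf`` extends the stop screen to the fixed part
    of the insert between the outermost loop anchors.
    """
    reasons: list[str] = []
    of = orient_and_frame(read, scaffold, max_anchor_mismatch, anchor_k)
    if of is None:
        return CloneRecord(
            read_id=read.read_id, oriented_dna=read.dna, orientation="unknown",
            frame_offset=0, protein="", loop_peptides={}, status="invalid",
            failure_reasons=["unalignable read"],
        )
    orientation, frame = of
    oriented = read.dna if orientation == "forward" else _revcomp(read.dna)

    for name, site in scaffold.required_sites:
        if site not in oriented:
            reasons.append(f"missing required site {name}")

    loops: dict[str, tuple[str, str]] = {}
    loop_spans: list[tuple[int, int]] = []
    for loop_id in scaffold.loops:
        span = _find_anchor_pair(oriented, scaffold, loop_id, max_anchor_mismatch, anchor_k)
        if span is None:
            reasons.append(f"loop {loop_id} anchors not found")
            continue
        start, end = span
        loop_dna = oriented[start:end]
        if len(loop_dna) % 3 != 0:
            reasons.append(f"loop {loop_id} length not a codon multiple")
            continue
        loop_spans.append(span)
        codons = [loop_dna[i: i + 3] for i in range(0, len(loop_dna), 3)]
        if any(c in STOP_CODONS for c in codons):
            reasons.append("stop codon in variable region")
        if "N" in loop_dna:
            reasons.append("ambiguous base in variable region")
        pep = "".join(
            "X" if "N" in c else str(Seq(c).translate()) for c in codons
        )
        loops[loop_id] = (loop_dna, pep)

    coding = oriented[frame:]
    coding = coding[: 3 * (len(coding) // 3)]
    protein = str(Seq(coding.replace("N", "A")).translate())

    if screen_whole_orf and loop_spans:
        lo = min(s for s, _ in loop_spans)
        hi = max(e for _, e in loop_spans)
        in_loop = set()
        for s, e in loop_spans:
            in_loop.update(range(s, e))
        for i in range(lo - ((lo - frame) % 3), hi, 3):
            if i < 0 or i + 3 > len(oriented) or i in in_loop:
                continue
            if oriented[i: i + 3] in STOP_CODONS:
                reasons.append("stop codon in open reading frame")
                break

    return CloneRecord(
        read_id=read.read_id,
        oriented_dna=oriented,
        orientation=orientation,
        frame_offset=frame,
        protein=protein,
        loop_peptides=loops,
        status="valid" if not reasons else "invalid",
        failure_reasons=reasons,
    )


def validate_reads(
    reads: list[ReadRecord], scaffold: ScaffoldTemplate, **kwargs
) -> list[CloneRecord]:
    """Screen a batch of reads; order of the output follows the input."""
    return [validate_clone(r, scaffold, **kwargs) for r in reads]
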