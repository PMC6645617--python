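"""Protein-level consequence of each isoform: PTC location and NMD heuristic.

Each mature mRNA is translated in the declared reading frame; the first
in-frame stop codon is reported as a premature termination codon (PTC)
with an HGVS-flavored description ``p.<RefAA><codon>*`` (the reference
amino acid is taken from the canonical transcript's codon at the same
number).  Nonsense-mediated decay is predicted with the standard 50-nt
rule: a transcript is an NMD substrate when its PTC lies more than 50 nt
upstream of the last exon-exon junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .gene_model import (
    IsoformSpec,
    MiniGene,
    SpliceOutcome,
    first_codon_number,
    inserted_sequence,
    splice_map,
)

_STOPS = {"TAA", "TAG", "TGA"}

NMD_THRESHOLD_NT = 50


class ConsequenceError(ValueError):
    pass


@dataclass(frozen=True)
class PtcSite:
    """First in-frame stop codon of a mature sequence.

    ``local_codon`` counts complete codons within the modeled sequence
    (1-based); ``codon_number`` adds the transcript-wide offset so reports
    show full-length numbering.  ``start``/``end`` are 1-based mature
    positions of the stop codon's first/last base.
    """

    local_codon: int
    codon_number: int
    start: int
    end: int
    codon: str


def translate_to_ptc(seq: str, phase: int, codon_offset: int = 0) -> PtcSite | None:
    """Scan codons from the declared frame; return the first stop, if any."""
    if len(seq) < 3:
        raise ConsequenceError("sequence must be at least one codon long")
    if not 0 <= phase <= 2:
        raise ConsequenceError("phase must be 0, 1 or 2")
    if set(seq) - set("ACGT"):
        raise ConsequenceError("sequence must be uppercase ACGT")
    start = (3 - phase) % 3
    local = 0
    for i in range(start, len(seq) - 2, 3):
        local += 1
        if seq[i : i + 3] in _STOPS:
            return PtcSite(local, local + codon_offset, i + 1, i + 3, seq[i : i + 3])
    return None


def nmd_rule(
    ptc_end: int, junctions: Sequence[int], threshold: int = NMD_THRESHOLD_NT
) -> bool:
    """True iff the PTC lies > ``threshold`` nt upstream of the last junction.

    ``ptc_end`` is the mature position of the stop codon's last base;
    ``junctions`` are mature positions of the last base before each
    exon-exon junction.  A transcript with no junction downstream of the
    PTC (PTC in the last exon) is not an NMD substrate.
    """
    if not junctions:
        return False
    return max(junctions) - ptc_end > threshold


@dataclass(frozen=True)
class ConsequenceCall:
    isoform: str
    inserted_len: int
    frame_preserving: bool
    ptc: PtcSite | None
    protein_description: str
    nmd_predicted: bool

    def to_dict(self) -> dict:
        d = {
            "isoform": self.isoform,
            "inserted_len": self.inserted_len,
            "frame_preserving": self.frame_preserving,
            "protein_description": self.protein_description,
            "nmd_predicted": self.nmd_predicted,
        }
        if self.ptc is not None:
            d["ptc_codon"] = self.ptc.codon_number
            d["ptc_local_codon"] = self.ptc.local_codon
            d["ptc_position"] = [self.ptc.start, self.ptc.end]
            d["ptc_stop_codon"] = self.ptc.codon
        else:
            d["ptc_codon"] = None
        return d


def _canonical_codon(gene: MiniGene, local_codon: int) -> str | None:
    canonical, _ = splice_map(gene, IsoformSpec.all_canonical(gene.n_introns))
    start = (3 - gene.phase) % 3 + 3 * (local_codon - 1)
    codon = canonical[start : start + 3]
    return codon if len(codon) == 3 else None


def annotate_isoform(
    gene: MiniGene,
    spec: IsoformSpec,
    isoform_name: str = "",
    nmd_threshold: int = NMD_THRESHOLD_NT,
) -> ConsequenceCall:
    """Translate one splice outcome and annotate its PTC/NMD consequence.

    ``gene`` should be the allele actually producing the isoform (the
    mutant allele for aberrant isoforms); the PTC itself is created by
    retained intronic sequence, not by the intronic substitution.
    """
    mature, junctions = splice_map(gene, spec)
    ins = inserted_sequence(gene, spec)
    offset = first_codon_number(gene) - 1
    ptc = translate_to_ptc(mature, gene.phase, offset)
    if ptc is None:
        desc = "p.="  # read-through of the modeled region: no stop found
        nmd = False
    else:
        ref_codon = _canonical_codon(gene, ptc.local_codon)
        if ref_codon is not None:
            aa = seq3(str(Seq(ref_codon).translate()))
            desc = f"p.{aa}{ptc.codon_number}*"
        else:
            desc = f"p.?{ptc.codon_number}*"
        nmd = nmd_rule(ptc.end, junctions, nmd_threshold)
    if not isoform_name:
        kinds = {out.kind for out in spec.outcomes}
        isoform_name = "canonical" if kinds == {SpliceOutcome.CANONICAL} else "aberrant"
    return ConsequenceCall(
        isoform=isoform_name,
        inserted_len=len(ins),
        frame_preserving=len(ins) % 3 == 0,
        ptc=ptc,
        protein_description=desc,
        nmd_predicted=nmd,
    )
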