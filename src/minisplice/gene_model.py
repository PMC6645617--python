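"""Mini-gene model: segments, coding-style coordinates, variants and splice outcomes.

A :class:`MiniGene` stores an amplicon-scale gene fragment in transcript
orientation as an alternating run of exon and intron segments.  Coding
(HGVS ``c.``-style) coordinates anchor the first base of the first modeled
exon, so intronic positions can be addressed as ``c.<anchor>+<offset>``
(e.g. a donor +5 position five bases into the downstream intron).  Splice
outcomes per intron — canonical excision, use of a cryptic donor that
retains the first *r* intronic bases, or full intron retention — are
described by :class:`IsoformSpec`, from which mature mRNA sequences and
inserted sequences are derived exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_DNA = frozenset("ACGT")

EXON = "exon"
INTRON = "intron"


class GeneModelError(ValueError):
    """Invalid mini-gene structure or splice specification."""


class CoordinateError(GeneModelError):
    """A coding-style coordinate does not address a modeled base."""


class ReferenceMismatchError(GeneModelError):
    """Variant reference base disagrees with the gene sequence."""


@dataclass(frozen=True)
class Segment:
    label: str
    role: str  # EXON or INTRON
    seq: str


@dataclass(frozen=True)
class CVariant:
    """Single-base substitution in coding-anchored coordinates.

    ``anchor`` is the coding coordinate of the nearest exonic base and
    ``offset`` the signed intronic offset (0 = exonic, +n = n bases into
    the downstream intron, -n = n bases into the upstream intron).
    """

    anchor: int
    offset: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for base, name in ((self.ref, "ref"), (self.alt, "alt")):
            if base not in _DNA:
                raise GeneModelError(f"{name} must be a single base in ACGT, got {base!r}")
        if self.ref == self.alt:
            raise GeneModelError("ref and alt must differ")

    def __str__(self) -> str:
        off = f"{self.offset:+d}" if self.offset else ""
        return f"c.{self.anchor}{off}{self.ref}>{self.alt}"


class SpliceOutcome(Enum):
    CANONICAL = "canonical"
    CRYPTIC_DONOR = "cryptic_donor"
    INTRON_RETENTION = "intron_retention"


@dataclass(frozen=True)
class IntronOutcome:
    kind: SpliceOutcome
    retained_len: int = 0

    def __post_init__(self) -> None:
        if self.kind is SpliceOutcome.CRYPTIC_DONOR:
            if self.retained_len <= 0:
                raise GeneModelError("CRYPTIC_DONOR requires a positive retained_len")
        elif self.retained_len:
            raise GeneModelError(f"retained_len is only meaningful for CRYPTIC_DONOR")


CANONICAL = IntronOutcome(SpliceOutcome.CANONICAL)
INTRON_RETENTION = IntronOutcome(SpliceOutcome.INTRON_RETENTION)


def cryptic_donor(retained_len: int) -> IntronOutcome:
    return IntronOutcome(SpliceOutcome.CRYPTIC_DONOR, retained_len)


@dataclass(frozen=True)
class IsoformSpec:
    """Per-intron splice outcome list, in intron order."""

    outcomes: tuple[IntronOutcome, ...]

    def __init__(self, outcomes) -> None:
        object.__setattr__(self, "outcomes", tuple(outcomes))

    @classmethod
    def all_canonical(cls, n_introns: int) -> "IsoformSpec":
        return cls((CANONICAL,) * n_introns)

    @classmethod
    def single(cls, n_introns: int, intron_index: int, outcome: IntronOutcome) -> "IsoformSpec":
        outs = [CANONICAL] * n_introns
        outs[intron_index] = outcome
        return cls(outs)


@dataclass(frozen=True)
class MiniGene:
    """Alternating exon/intron segments with a coding-coordinate anchor.

    ``coding_anchor`` is the c.-coordinate of the first base of the first
    exon; ``phase`` (0-2) is that base's position within its codon
    (0 = first base of a codon).  Introns must start GT and end AG unless
    ``enforce_canonical`` is disabled (used only for negative fixtures).
    """

    name: str
    segments: tuple[Segment, ...]
    coding_anchor: int
    phase: int
    enforce_canonical: bool = True

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs or segs[0].role != EXON or segs[-1].role != EXON:
            raise GeneModelError("segments must begin and end with an exon")
        for i, seg in enumerate(segs):
            expected = EXON if i % 2 == 0 else INTRON
            if seg.role != expected:
                raise GeneModelError("segments must strictly alternate exon/intron")
            if not seg.seq or set(seg.seq) - _DNA:
                raise GeneModelError(f"segment {seg.label}: sequence must be non-empty ACGT")
            if seg.role == INTRON and self.enforce_canonical:
                if not (seg.seq.startswith("GT") and seg.seq.endswith("AG")):
                    raise GeneModelError(
                        f"intron {seg.label} violates the canonical GT...AG rule"
                    )
        if len({s.label for s in segs}) != len(segs):
            raise GeneModelError("segment labels must be unique")
        if not 0 <= self.phase <= 2:
            raise GeneModelError("phase must be 0, 1 or 2")

    # -- structural accessors -------------------------------------------------

    @property
    def exons(self) -> tuple[Segment, ...]:
        return self.segments[::2]

    @property
    def introns(self) -> tuple[Segment, ...]:
        return self.segments[1::2]

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise GeneModelError(f"no segment named {label!r}")

    def intron_index(self, label: str) -> int:
        for i, seg in enumerate(self.introns):
            if seg.label == label:
                return i
        raise GeneModelError(f"no intron named {label!r}")

    def exon_coding_ranges(self) -> list[tuple[int, int]]:
        """(first, last) coding coordinate of each exon, strictly increasing."""
        ranges = []
        start = self.coding_anchor
        for exon in self.exons:
            ranges.append((start, start + len(exon.seq) - 1))
            start += len(exon.seq)
        return ranges

    def iter_addressable(self) -> Iterator[tuple[int, int]]:
        """Yield every (anchor, offset) pair addressing a base of the gene."""
        ranges = self.exon_coding_ranges()
        for (lo, hi) in ranges:
            for c in range(lo, hi + 1):
                yield (c, 0)
        for i, intron in enumerate(self.introns):
            n = len(intron.seq)
            left_anchor = ranges[i][1]
            right_anchor = ranges[i + 1][0]
            half = (n + 1) // 2
            for p in range(1, n + 1):
                if p <= half:
                    yield (left_anchor, p)
                else:
                    yield (right_anchor, -(n - p + 1))


# -- coordinate resolution ----------------------------------------------------


def resolve_position(gene: MiniGene, anchor: int, offset: int) -> tuple[str, int]:
    """Map a c.-style (anchor, offset) to (segment label, 1-based position).

    ``offset`` 0 addresses the exonic base itself; positive offsets count
    into the downstream intron from the anchor exon's last base, negative
    offsets into the upstream intron from the anchor exon's first base.
    """
    ranges = gene.exon_coding_ranges()
    exon_idx = None
    for i, (lo, hi) in enumerate(ranges):
        if lo <= anchor <= hi:
            exon_idx = i
            break
    if exon_idx is None:
        raise CoordinateError(f"anchor c.{anchor} is outside the modeled coding range")
    lo, hi = ranges[exon_idx]
    if offset == 0:
        exon = gene.exons[exon_idx]
        return exon.label, anchor - lo + 1
    if offset > 0:
        if anchor != hi:
            raise CoordinateError(
                f"c.{anchor}+{offset}: positive offsets require the last base of an exon"
            )
        if exon_idx >= gene.n_introns:
            raise CoordinateError(f"c.{anchor}+{offset}: no intron downstream of the last exon")
        intron = gene.introns[exon_idx]
        if offset > len(intron.seq):
            raise CoordinateError(
                f"c.{anchor}+{offset}: offset exceeds intron length {len(intron.seq)}"
            )
        return intron.label, offset
    # offset < 0
    if anchor != lo:
        raise CoordinateError(
            f"c.{anchor}{offset}: negative offsets require the first base of an exon"
        )
    if exon_idx == 0:
        raise CoordinateError(f"c.{anchor}{offset}: no intron upstream of the first exon")
    intron = gene.introns[exon_idx - 1]
    if -offset > len(intron.seq):
        raise CoordinateError(
            f"c.{anchor}{offset}: offset exceeds intron length {len(intron.seq)}"
        )
    return intron.label, len(intron.seq) + offset + 1


def position_to_coding(gene: MiniGene, label: str, pos: int) -> tuple[int, int]:
    """Inverse of :func:`resolve_position` using nearest-exon anchoring."""
    seg = gene.segment(label)
    if not 1 <= pos <= len(seg.seq):
        raise CoordinateError(f"{label}: position {pos} outside segment of length {len(seg.seq)}")
    ranges = gene.exon_coding_ranges()
    if seg.role == EXON:
        idx = [e.label for e in gene.exons].index(label)
        return ranges[idx][0] + pos - 1, 0
    idx = gene.intron_index(label)
    n = len(seg.seq)
    if pos <= (n + 1) // 2:
        return ranges[idx][1], pos
    return ranges[idx + 1][0], -(n - pos + 1)


def base_at(gene: MiniGene, anchor: int, offset: int) -> str:
    label, pos = resolve_position(gene, anchor, offset)
    return gene.segment(label).seq[pos - 1]


def apply_variant(gene: MiniGene, v: CVariant) -> MiniGene:
    """Return the mutant allele carrying ``v``; the input gene is unchanged."""
    label, pos = resolve_position(gene, v.anchor, v.offset)
    seg = gene.segment(label)
    found = seg.seq[pos - 1]
    if found != v.ref:
        raise ReferenceMismatchError(
            f"{v}: reference base at {label}:{pos} is {found}, not {v.ref}"
        )
    new_seq = seg.seq[: pos - 1] + v.alt + seg.seq[pos:]
    new_segments = tuple(
        Segment(s.label, s.role, new_seq) if s.label == label else s for s in gene.segments
    )
    # a +5 substitution never touches the GT/AG dinucleotides, but a variant
    # at +1/+2 legitimately can: keep the object constructible for scoring.
    enforce = gene.enforce_canonical
    if seg.role == INTRON and (pos <= 2 or pos >= len(seg.seq) - 1):
        enforce = False
    return MiniGene(gene.name, new_segments, gene.coding_anchor, gene.phase, enforce)


# -- splicing -----------------------------------------------------------------


def _validate_spec(gene: MiniGene, spec: IsoformSpec) -> None:
    if len(spec.outcomes) != gene.n_introns:
        raise GeneModelError(
            f"isoform spec lists {len(spec.outcomes)} outcomes for {gene.n_introns} introns"
        )
    for intron, out in zip(gene.introns, spec.outcomes):
        if out.kind is SpliceOutcome.CRYPTIC_DONOR:
            r = out.retained_len
            if r >= len(intron.seq):
                raise GeneModelError(
                    f"{intron.label}: retained_len {r} must be < intron length {len(intron.seq)}"
                )
            if intron.seq[r : r + 2] != "GT":
                raise GeneModelError(
                    f"{intron.label}: cryptic donor requires GT at intron positions "
                    f"+{r + 1}/+{r + 2}, found {intron.seq[r:r + 2]!r}"
                )


def splice_map(gene: MiniGene, spec: IsoformSpec) -> tuple[str, list[int]]:
    """Mature mRNA plus splice-junction positions.

    Junction positions are 1-based positions in the mature sequence of the
    last base preceding each point where intronic sequence was excised
    (full intron retention produces no junction at that intron).
    """
    _validate_spec(gene, spec)
    parts: list[str] = []
    junctions: list[int] = []
    length = 0
    for i, exon in enumerate(gene.exons):
        parts.append(exon.seq)
        length += len(exon.seq)
        if i < gene.n_introns:
            out = spec.outcomes[i]
            intron = gene.introns[i]
            if out.kind is SpliceOutcome.CANONICAL:
                junctions.append(length)
            elif out.kind is SpliceOutcome.CRYPTIC_DONOR:
                parts.append(intron.seq[: out.retained_len])
                length += out.retained_len
                junctions.append(length)
            else:  # full retention: no splice, no junction
                parts.append(intron.seq)
                length += len(intron.seq)
    return "".join(parts), junctions


def splice(gene: MiniGene, spec: IsoformSpec) -> str:
    """Mature mRNA for the given per-intron splice outcomes."""
    return splice_map(gene, spec)[0]


def inserted_sequence(gene: MiniGene, spec: IsoformSpec) -> str:
    """Sequence inserted relative to the canonical transcript.

    Supports at most one aberrant intron (the assay models single events).
    """
    _validate_spec(gene, spec)
    aberrant = [
        (i, out) for i, out in enumerate(spec.outcomes) if out.kind is not SpliceOutcome.CANONICAL
    ]
    if not aberrant:
        return ""
    if len(aberrant) > 1:
        raise GeneModelError("multi-intron aberrations are unsupported")
    i, out = aberrant[0]
    intron = gene.introns[i]
    if out.kind is SpliceOutcome.CRYPTIC_DONOR:
        return intron.seq[: out.retained_len]
    return intron.seq


def shared_prefix_len(a: str, b: str) -> int:
    """Length of the longest common prefix of two sequences."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


# -- translation helpers ------------------------------------------------------


def translate_frame(seq: str, phase: int) -> str:
    """Translate from the first complete codon given the phase of base 1."""
    start = (3 - phase) % 3
    trimmed = seq[start : start + 3 * ((len(seq) - start) // 3)]
    return str(Seq(trimmed).translate())


def first_codon_number(gene: MiniGene) -> int:
    """Codon number (transcript-wide) of the first complete codon in the model."""
    first_complete_c = gene.coding_anchor + (3 - gene.phase) % 3
    return (first_complete_c + 2) // 3


# -- serialization ------------------------------------------------------------


def write_minigene(gene: MiniGene, fasta_path: str | Path, json_path: str | Path) -> None:
    """Write segments as multi-record FASTA plus a JSON coordinate sidecar."""
    records = [
        SeqRecord(Seq(s.seq), id=f"{gene.name}|{s.label}|{s.role}", description="")
        for s in gene.segments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = {
        "name": gene.name,
        "coding_anchor": gene.coding_anchor,
        "phase": gene.phase,
        "enforce_canonical": gene.enforce_canonical,
    }
    Path(json_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_minigene(fasta_path: str | Path, json_path: str | Path) -> MiniGene:
    meta = json.loads(Path(json_path).read_text())
    segments = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        try:
            name, label, role = rec.id.split("|")
        except ValueError as exc:
            raise GeneModelError(f"malformed FASTA header {rec.id!r}") from exc
        segments.append(Segment(label, role, str(rec.seq).upper()))
    return MiniGene(
        meta["name"],
        tuple(segments),
        meta["coding_anchor"],
        meta["phase"],
        meta.get("enforce_canonical", True),
    )
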