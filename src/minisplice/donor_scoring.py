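"""Position-weight-matrix scoring of 5' splice-donor sites.

A transparent log-odds PWM over the canonical 9-mer donor context (last 3
exonic bases, first 6 intronic bases; consensus (C/A)AG|GTRAGT) built from
a bundled table of human donor-site base frequencies.  It supports scoring
individual sites, computing a variant's delta score at a modeled donor,
and scanning an intron for cryptic GT donor candidates.  Scores are in
bits versus a uniform 0.25 background; only the sign/ordering of scores is
relied upon downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gene_model import CVariant, MiniGene, apply_variant, resolve_position

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Human 5' splice-donor base frequencies (percent) at positions -3..+6,
#: rows ordered A, C, G, T.  Values follow the classical splice-site
#: compilation surveys of human donor sites.
DONOR_FREQS_PCT = np.array(
    [
        #  A    C    G    T
        [33.0, 37.0, 18.0, 12.0],  # -3
        [60.0, 13.0, 14.0, 13.0],  # -2
        [8.0, 4.0, 81.0, 7.0],  # -1
        [0.0, 0.0, 100.0, 0.0],  # +1
        [0.0, 0.0, 0.0, 100.0],  # +2
        [59.0, 3.0, 35.0, 3.0],  # +3
        [72.0, 8.0, 12.0, 8.0],  # +4
        [6.0, 6.0, 84.0, 4.0],  # +5
        [15.0, 17.0, 19.0, 49.0],  # +6
    ]
)

POSITION_LABELS = ("-3", "-2", "-1", "+1", "+2", "+3", "+4", "+5", "+6")


class DonorScoringError(ValueError):
    pass


@dataclass(frozen=True)
class DonorPWM:
    """9 x 4 log2-odds matrix versus a uniform 0.25 background."""

    log_odds: np.ndarray

    @classmethod
    def from_frequencies(cls, freqs_pct: np.ndarray, pseudo: float = 1e-3) -> "DonorPWM":
        f = np.asarray(freqs_pct, dtype=float) / 100.0
        if f.shape != (9, 4):
            raise DonorScoringError("frequency table must be 9 positions x 4 bases")
        f = (f + pseudo) / (1.0 + 4.0 * pseudo)
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise DonorScoringError("per-position frequencies must sum to 1")
        return cls(np.log2(f / 0.25))

    @classmethod
    def default(cls) -> "DonorPWM":
        return cls.from_frequencies(DONOR_FREQS_PCT)

    @classmethod
    def uniform(cls) -> "DonorPWM":
        return cls.from_frequencies(np.full((9, 4), 25.0), pseudo=0.0)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.log_odds.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


def score_site(pwm: DonorPWM, ninemer: str) -> float:
    """Sum of per-position log2 odds for a donor 9-mer."""
    if len(ninemer) != 9:
        raise DonorScoringError(f"donor context must be 9 bases, got {len(ninemer)}")
    try:
        idx = [_BASE_INDEX[b] for b in ninemer]
    except KeyError as exc:
        raise DonorScoringError(f"invalid base in {ninemer!r}") from exc
    return float(pwm.log_odds[np.arange(9), idx].sum())


@dataclass(frozen=True)
class DonorSiteCall:
    """A candidate GT donor within an intron.

    ``offset`` is the 1-based intron position of the first base of the GT
    (the native donor is offset 1; a cryptic donor retaining r bases sits
    at offset r+1).
    """

    offset: int
    score: float
    context: str

    def __post_init__(self) -> None:
        if self.context[3:5] != "GT":
            raise DonorScoringError("donor context must have GT at its +1/+2 positions")


def _intron_context(gene: MiniGene, intron_label: str) -> tuple[str, int]:
    """Concatenated flanking-exon/intron/exon sequence and intron start index."""
    idx = gene.intron_index(intron_label)
    up = gene.exons[idx].seq
    intron = gene.introns[idx].seq
    down = gene.exons[idx + 1].seq
    return up + intron + down, len(up)


def donor_ninemer(gene: MiniGene, intron_label: str, offset: int = 1) -> str:
    """Donor 9-mer context for a GT whose first base is at intron ``offset``."""
    ctx, b = _intron_context(gene, intron_label)
    gt = b + offset - 1
    if gt - 3 < 0 or gt + 6 > len(ctx):
        raise DonorScoringError(f"offset {offset} leaves an incomplete 9-mer context")
    return ctx[gt - 3 : gt + 6]


def _variant_donor(gene: MiniGene, v: CVariant) -> str:
    """Label of the modeled (native) donor whose 9-mer window contains v."""
    label, pos = resolve_position(gene, v.anchor, v.offset)
    seg = gene.segment(label)
    if seg.role == "intron":
        if v.offset > 0 and pos <= 6:
            return label
        raise DonorScoringError(f"{v}: not within +1..+6 of a donor")
    # exonic: must be one of the last 3 bases of an exon followed by an intron
    exon_idx = [e.label for e in gene.exons].index(label)
    if exon_idx < gene.n_introns and pos > len(seg.seq) - 3:
        return gene.introns[exon_idx].label
    raise DonorScoringError(f"{v}: not within the -3..-1 window of a modeled donor")


def delta_variant(
    pwm: DonorPWM, gene: MiniGene, v: CVariant
) -> tuple[float, float, float]:
    """(score_ref, score_alt, delta) at the native donor containing ``v``."""
    intron_label = _variant_donor(gene, v)
    mutant = apply_variant(gene, v)
    score_ref = score_site(pwm, donor_ninemer(gene, intron_label))
    score_alt = score_site(pwm, donor_ninemer(mutant, intron_label))
    return score_ref, score_alt, score_alt - score_ref


def scan_cryptic(
    pwm: DonorPWM, gene: MiniGene, intron_label: str, max_offset: int
) -> list[DonorSiteCall]:
    """Score every GT dinucleotide at intron offsets 1..max_offset.

    Returns calls ranked by score descending, ties broken by smaller
    offset.  An intron with no GT in range yields an empty list.
    """
    intron = gene.segment(intron_label)
    if intron.role != "intron":
        raise DonorScoringError(f"{intron_label} is not an intron")
    if max_offset < 1 or max_offset > len(intron.seq) - 2:
        raise DonorScoringError(
            f"max_offset must be in [1, {len(intron.seq) - 2}] for {intron_label}"
        )
    calls = []
    for k in range(1, max_offset + 1):
        if intron.seq[k - 1 : k + 1] == "GT":
            nm = donor_ninemer(gene, intron_label, k)
            calls.append(DonorSiteCall(k, score_site(pwm, nm), nm))
    calls.sort(key=lambda c: (-c.score, c.offset))
    return calls


def scan_to_frame(calls: list[DonorSiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": [c.offset for c in calls],
            "score_bits": [c.score for c in calls],
            "context": [c.context for c in calls],
        }
    )
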