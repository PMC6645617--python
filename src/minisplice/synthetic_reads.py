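"""Fixture construction and labeled amplicon-read simulation.

The default fixture emulates a four-exon mini-gene modeled on the
amplified region of a membrane-transporter transcript: a 130-bp first
intron whose donor carries a +5 G>A substitution on one allele, a cryptic
GT donor 7 bp downstream of the native donor (so that cryptic splicing
retains 6 nt), and an exon ending ...TA so that the first retained
intronic base (G) completes an immediate in-frame TAG stop.  Reads are
single-end with uniform start positions within each isoform, constant
Q37 qualities and substitution-only errors; every read carries a ground
truth record (source allele, source isoform, informativeness flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classifier as clf
from .gene_model import (
    CVariant,
    INTRON_RETENTION,
    IsoformSpec,
    MiniGene,
    Segment,
    apply_variant,
    base_at,
    cryptic_donor,
    resolve_position,
    splice,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

ALLELE_REF = "ref"
ALLELE_MUT = "mut"

TRUTH_COLUMNS = ["read_id", "allele", "category", "junction_informative", "covers_variant"]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureConfig:
    """Geometry and variant of the default mini-gene fixture.

    Exon/intron lengths default to an amplicon-scale gene with a 130-bp
    first intron; ``coding_anchor`` 2121 places the first-intron donor
    boundary at c.2240, so the default variant reads c.2240+5G>A and the
    stop created by retained intronic sequence falls in codon 747.
    """

    exon_lens: tuple[int, int, int, int] = (120, 80, 90, 110)
    intron_lens: tuple[int, int, int] = (130, 90, 100)
    coding_anchor: int = 2121
    first_exon_number: int = 16
    variant_offset: int = 5
    variant_alt: str = "A"
    retained_len: int = 6
    seed: int = 2019
    name: str = "SLC4A11-mini"

    # first 6 intronic bases; +5 G is the variant's reference base
    _DONOR_PREFIX = "GTAAGG"
    # near-consensus cryptic donor placed at +retained_len+1
    _CRYPTIC_MOTIF = "GTAAGT"

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.exon_lens + self.intron_lens):
            raise SimulationError("segment lengths must be positive")
        e1 = self.exon_lens[0]
        phase = (self.coding_anchor - 1) % 3
        if (phase + e1 - 2) % 3 != 0:
            raise SimulationError(
                "first-exon length and coding_anchor must put the final TA in-frame "
                "(the codon completed by the first retained intronic base)"
            )
        if e1 < 2 or self.exon_lens[1] < 2:
            raise SimulationError("first two exons must each be at least 2 bp")
        r = self.retained_len
        if r < len(self._DONOR_PREFIX):
            raise SimulationError("retained_len must be >= 6 (cryptic GT beyond the +5 window)")
        if r + len(self._CRYPTIC_MOTIF) > self.intron_lens[0] - 2:
            raise SimulationError("first intron too short for the cryptic donor motif")
        if any(l < 4 for l in self.intron_lens):
            raise SimulationError("introns must be at least 4 bp (GT...AG)")
        if not 1 <= self.variant_offset <= len(self._DONOR_PREFIX):
            raise SimulationError("variant offset must address the donor +1..+6 window")
        ref = self._DONOR_PREFIX[self.variant_offset - 1]
        if self.variant_alt == ref:
            raise SimulationError(f"variant alt equals the pinned reference base {ref}")

    @property
    def phase(self) -> int:
        return (self.coding_anchor - 1) % 3

    @property
    def variant(self) -> CVariant:
        anchor = self.coding_anchor + self.exon_lens[0] - 1
        ref = self._DONOR_PREFIX[self.variant_offset - 1]
        return CVariant(anchor, self.variant_offset, ref, self.variant_alt)


_STOPS = {"TAA", "TAG", "TGA"}


def build_fixture(cfg: FixtureConfig = FixtureConfig()) -> MiniGene:
    """Deterministically build the mini-gene for ``cfg``.

    Filler sequence is seeded-random; the constrained positions (donor
    prefix, cryptic motif, exon-terminal TA, downstream-exon CA, intron
    ends) are pinned, and in-frame stop codons are scrubbed from the
    canonical transcript so the only PTC is the one the aberrant isoforms
    create.
    """
    rng = np.random.default_rng(cfg.seed)
    e1 = cfg.exon_lens[0]
    total_exonic = sum(cfg.exon_lens)

    coding = rng.integers(0, 4, size=total_exonic)
    coding = [  # as list of chars
        "ACGT"[i] for i in coding
    ]
    # pinned: exon-1 ends TA; exon-2 begins CA (keeps the straddling codon
    # TAC stop-free and separates the retention signature from exon sequence)
    coding[e1 - 2 : e1 + 2] = list("TACA")
    # scrub in-frame stops from the canonical transcript
    start = (3 - cfg.phase) % 3
    for i in range(start, total_exonic - 2, 3):
        if "".join(coding[i : i + 3]) in _STOPS:
            coding[i + 2] = "C"
    canonical = "".join(coding)

    exon_seqs = []
    pos = 0
    for ln in cfg.exon_lens:
        exon_seqs.append(canonical[pos : pos + ln])
        pos += ln

    intron_seqs = []
    for k, ln in enumerate(cfg.intron_lens):
        arr = ["ACGT"[i] for i in rng.integers(0, 4, size=ln)]
        if k == 0:
            arr[: len(cfg._DONOR_PREFIX)] = list(cfg._DONOR_PREFIX)
            r = cfg.retained_len
            arr[r : r + len(cfg._CRYPTIC_MOTIF)] = list(cfg._CRYPTIC_MOTIF)
        else:
            arr[:2] = list("GT")
        arr[-2:] = list("AG")
        intron_seqs.append("".join(arr))

    segments = []
    for i in range(len(cfg.exon_lens)):
        n = cfg.first_exon_number + i
        segments.append(Segment(f"exon{n}", "exon", exon_seqs[i]))
        if i < len(cfg.intron_lens):
            segments.append(Segment(f"intron{n}", "intron", intron_seqs[i]))

    gene = MiniGene(cfg.name, tuple(segments), cfg.coding_anchor, cfg.phase)
    v = cfg.variant
    if base_at(gene, v.anchor, v.offset) != v.ref:
        raise SimulationError("pinned donor prefix does not match the configured variant")
    return gene


# -- read sets ----------------------------------------------------------------


@dataclass(frozen=True)
class ReadSetSpec:
    """Stochastic amplicon read-set specification (heterozygote model).

    ``mut_fraction`` is the fraction of transcripts drawn from the mutant
    allele (0.5 for a balanced heterozygote).  The wild-type allele
    splices canonically; the mutant allele emits a mixture of canonical,
    cryptic-donor and retention transcripts.  The default mutant mixture
    yields overall read-category proportions (0.5823, 0.3275, 0.0902).
    """

    n: int
    seed: int
    read_len: int = 150
    error_rate: float = 0.001
    mut_fraction: float = 0.5
    mut_mixture: Mapping[str, float] = field(
        default_factory=lambda: {clf.WT: 0.1646, clf.INS6: 0.655, clf.RETENTION: 0.1804}
    )

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise SimulationError("n must be positive")
        if self.read_len < 1:
            raise SimulationError("read_len must be positive")
        if not 0 <= self.error_rate < 1:
            raise SimulationError("error_rate must be in [0, 1)")
        if not 0 <= self.mut_fraction <= 1:
            raise SimulationError("mut_fraction must be in [0, 1]")
        mix = dict(self.mut_mixture)
        if set(mix) - set(clf.ISOFORM_CATEGORIES):
            raise SimulationError(f"unknown categories in mut_mixture: {set(mix)}")
        if any(p < 0 for p in mix.values()):
            raise SimulationError("mixture proportions must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise SimulationError("mut_mixture must sum to 1 within 1e-9")

    def overall_proportions(self) -> dict[str, float]:
        """Read-level category proportions implied by allele mixing."""
        props = {cat: 0.0 for cat in clf.ISOFORM_CATEGORIES}
        props[clf.WT] += 1.0 - self.mut_fraction
        for cat, p in self.mut_mixture.items():
            props[cat] += self.mut_fraction * p
        return props


@dataclass
class ReadSet:
    ids: list[str]
    seqs: list[str]
    truth: pd.DataFrame

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.seqs):
                fh.write(f"@{rid}\n{seq}\n+\n{'F' * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _isoform_table(gene: MiniGene, variant: CVariant, retained_len: int):
    """Sequences and variant positions for the closed isoform set."""
    label, pos = resolve_position(gene, variant.anchor, variant.offset)
    idx = gene.intron_index(label)
    mutant = apply_variant(gene, variant)
    n_int = gene.n_introns
    upstream = sum(len(e.seq) for e in gene.exons[: idx + 1])
    var_pos = upstream + pos - 1  # 0-based in isoforms that retain it
    return {
        (ALLELE_REF, clf.WT): (splice(gene, IsoformSpec.all_canonical(n_int)), None),
        (ALLELE_MUT, clf.WT): (splice(mutant, IsoformSpec.all_canonical(n_int)), None),
        (ALLELE_MUT, clf.INS6): (
            splice(mutant, IsoformSpec.single(n_int, idx, cryptic_donor(retained_len))),
            var_pos if pos <= retained_len else None,
        ),
        (ALLELE_MUT, clf.RETENTION): (
            splice(mutant, IsoformSpec.single(n_int, idx, INTRON_RETENTION)),
            var_pos,
        ),
    }


def _informative_lookup(signatures, category: str, iso_len: int, read_len: int) -> np.ndarray:
    """Boolean per start position: does the read fully contain a window?"""
    n_starts = iso_len - read_len + 1
    ok = np.zeros(max(n_starts, 0), dtype=bool)
    for a, b, _ in clf.category_windows(signatures, category):
        lo = max(0, b - read_len)
        hi = min(a, n_starts - 1)
        if lo <= hi:
            ok[lo : hi + 1] = True
    return ok


def _decode_rows(mat: np.ndarray) -> list[str]:
    chars = _BASES[mat]
    return [row.tobytes().decode("ascii") for row in chars]


def simulate_reads(
    gene: MiniGene,
    spec: ReadSetSpec,
    variant: CVariant,
    retained_len: int = 6,
    params: clf.ClassifierParams = clf.ClassifierParams(),
) -> ReadSet:
    """Simulate a labeled single-end read set from the heterozygote model.

    Deterministic given ``spec.seed``; with ``error_rate`` 0 every read is
    an exact substring of its source isoform's mature sequence.
    """
    isoforms = _isoform_table(gene, variant, retained_len, )
    signatures = clf.build_signatures(gene, variant, retained_len, params)
    R = spec.read_len
    for (allele, cat), (seq, _) in isoforms.items():
        if R > len(seq):
            raise SimulationError(
                f"read length {R} exceeds the {allele}/{cat} isoform length {len(seq)}"
            )

    rng = np.random.default_rng(spec.seed)
    n = spec.n
    is_mut = rng.random(n) < spec.mut_fraction
    u_cat = rng.random(n)
    u_start = rng.random(n)

    mix_cats = list(clf.ISOFORM_CATEGORIES)
    mut_cum = np.cumsum([spec.mut_mixture.get(c, 0.0) for c in mix_cats])
    cat_idx = np.zeros(n, dtype=int)  # ref allele -> WT
    cat_idx[is_mut] = np.searchsorted(mut_cum, u_cat[is_mut], side="right").clip(
        0, len(mix_cats) - 1
    )
    categories = np.array(mix_cats, dtype=object)[cat_idx]

    keys = [(ALLELE_MUT if m else ALLELE_REF, c) for m, c in zip(is_mut, categories)]
    iso_arrays = {
        k: _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for k, (seq, _) in isoforms.items()
    }
    lookups = {
        (allele, cat): _informative_lookup(signatures, cat, len(seq), R)
        for (allele, cat), (seq, _) in isoforms.items()
    }

    reads = np.empty((n, R), dtype=np.uint8)
    starts = np.empty(n, dtype=int)
    informative = np.zeros(n, dtype=bool)
    covers = np.zeros(n, dtype=bool)
    offsets = np.arange(R)
    for key, (seq, var_pos) in isoforms.items():
        mask = np.array([k == key for k in keys])
        if not mask.any():
            continue
        n_starts = len(seq) - R + 1
        s = (u_start[mask] * n_starts).astype(int).clip(0, n_starts - 1)
        starts[mask] = s
        reads[mask] = iso_arrays[key][s[:, None] + offsets]
        informative[mask] = lookups[key][s]
        if var_pos is not None:
            covers[mask] = (s <= var_pos) & (var_pos < s + R)

    if spec.error_rate > 0:
        err = rng.random((n, R)) < spec.error_rate
        k = int(err.sum())
        if k:
            shift = rng.integers(1, 4, size=k).astype(np.uint8)
            reads[err] = (reads[err] + shift) % 4

    ids = [f"r{i:06d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "read_id": ids,
            "allele": [k[0] for k in keys],
            "category": categories,
            "junction_informative": informative,
            "covers_variant": covers,
        }
    )
    return ReadSet(ids, _decode_rows(reads), truth)


def make_exact_counts_readset(
    gene: MiniGene,
    counts: Mapping[str, int],
    variant: CVariant,
    retained_len: int = 6,
    read_len: int = 150,
    params: clf.ClassifierParams = clf.ClassifierParams(),
) -> ReadSet:
    """Error-free read set with exact per-category counts.

    Every read is guaranteed junction-informative (its start cycles over
    the isoform's informative start positions), so downstream
    classification reproduces ``counts`` exactly.
    """
    if set(counts) - set(clf.ISOFORM_CATEGORIES):
        raise SimulationError(f"unknown categories: {set(counts) - set(clf.ISOFORM_CATEGORIES)}")
    if any(c < 0 for c in counts.values()):
        raise SimulationError("counts must be non-negative")
    if sum(counts.values()) == 0:
        raise SimulationError("total read count must be positive")

    isoforms = _isoform_table(gene, variant, retained_len)
    signatures = clf.build_signatures(gene, variant, retained_len, params)

    ids: list[str] = []
    seqs: list[str] = []
    rows = []
    i = 0
    for cat in clf.ISOFORM_CATEGORIES:
        want = int(counts.get(cat, 0))
        if want == 0:
            continue
        allele = ALLELE_REF if cat == clf.WT else ALLELE_MUT
        seq, var_pos = isoforms[(allele, cat)]
        if read_len > len(seq):
            raise SimulationError(f"read length {read_len} exceeds {cat} isoform length")
        lookup = _informative_lookup(signatures, cat, len(seq), read_len)
        informative_starts = np.flatnonzero(lookup)
        if informative_starts.size == 0:
            raise SimulationError(f"no informative start positions for {cat}")
        for j in range(want):
            s = int(informative_starts[j % informative_starts.size])
            rid = f"x{i:06d}"
            ids.append(rid)
            seqs.append(seq[s : s + read_len])
            rows.append(
                {
                    "read_id": rid,
                    "allele": allele,
                    "category": cat,
                    "junction_informative": True,
                    "covers_variant": bool(
                        var_pos is not None and s <= var_pos < s + read_len
                    ),
                }
            )
            i += 1
    return ReadSet(ids, seqs, pd.DataFrame(rows, columns=TRUTH_COLUMNS))


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
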