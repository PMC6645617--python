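"""Junction-signature read classifier.

Each of the closed set of isoforms produced by the assay (wild-type,
cryptic-donor insertion, full intron retention) is diagnosed by a short
anchor sequence centered on the junction or exon/intron boundary that is
unique to it.  A read is assigned to the unique category whose signature
occurs within it with at most ``max_mismatches`` substitutions (exact
sliding-window Hamming comparison, no indels); reads touching no
signature window are AMBIGUOUS, reads matching signatures of two distinct
categories are CONFLICT.  Because the amplicon is short and the isoform
set closed, this replaces spliced alignment and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

from .gene_model import (
    CVariant,
    INTRON_RETENTION,
    IsoformSpec,
    MiniGene,
    apply_variant,
    cryptic_donor,
    resolve_position,
    splice,
)

# read categories
WT = "WT"
INS6 = "INS6"
RETENTION = "RETENTION"
AMBIGUOUS = "AMBIGUOUS"
CONFLICT = "CONFLICT"

CATEGORIES = (WT, INS6, RETENTION, AMBIGUOUS, CONFLICT)
ISOFORM_CATEGORIES = (WT, INS6, RETENTION)

ALLELE_REF = "ref"
ALLELE_ALT = "alt"
ALLELE_OTHER = "other"
ALLELE_NOT_COVERED = "not_covered"


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierParams:
    min_overhang: int = 8
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if self.min_overhang < 4:
            raise ClassifierError("min_overhang must be >= 4")
        if not 0 <= self.max_mismatches < self.min_overhang:
            raise ClassifierError("max_mismatches must be in [0, min_overhang)")

    @property
    def window(self) -> int:
        return 2 * self.min_overhang


@dataclass(frozen=True)
class JunctionSignature:
    """Diagnostic anchor of length 2*min_overhang centered on a junction.

    ``junction_pos`` is the 1-based mature-sequence position of the last
    base before the diagnostic junction/boundary; ``window_start`` the
    0-based start of the anchor within the isoform; ``variant_pos`` the
    0-based isoform position of the phased intronic variant base, when
    that base is part of the isoform.
    """

    name: str
    category: str
    anchor: str
    window_start: int
    junction_pos: int
    isoform_len: int
    variant_pos: int | None


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    category: str
    mismatches: int
    allele: str


def build_signatures(
    gene: MiniGene,
    variant: CVariant,
    retained_len: int,
    params: ClassifierParams = ClassifierParams(),
) -> list[JunctionSignature]:
    """Derive the four diagnostic signatures from the mini-gene.

    The aberrant isoforms are modeled on the mutant allele (they carry the
    intronic variant base within their retained sequence); the wild-type
    junction is allele-blind because the intron is excised.  Raises if any
    signature also occurs, within ``max_mismatches``, in an isoform of a
    different category — in that degenerate case a larger ``min_overhang``
    is required.
    """
    if variant.offset == 0:
        raise ClassifierError("the phased variant must be intronic (offset != 0)")
    label, pos = resolve_position(gene, variant.anchor, variant.offset)
    mutant = apply_variant(gene, variant)
    idx = gene.intron_index(label)
    n_int = gene.n_introns
    intron_len = len(gene.introns[idx].seq)

    canonical = splice(gene, IsoformSpec.all_canonical(n_int))
    ins = splice(mutant, IsoformSpec.single(n_int, idx, cryptic_donor(retained_len)))
    ret = splice(mutant, IsoformSpec.single(n_int, idx, INTRON_RETENTION))

    upstream_exon_len = sum(len(e.seq) for e in gene.exons[: idx + 1])
    mo = params.min_overhang
    w = params.window

    def window_at(iso: str, junction: int, category: str, name: str, varpos: int | None):
        start = junction - mo
        if start < 0 or start + w > len(iso):
            raise ClassifierError(
                f"signature {name}: window [{start}, {start + w}) outside isoform"
            )
        return JunctionSignature(
            name, category, iso[start : start + w], start, junction, len(iso), varpos
        )

    var_iso_pos = upstream_exon_len + pos - 1  # 0-based, in ins/ret isoforms
    sigs = [
        window_at(canonical, upstream_exon_len, WT, "wt_junction", None),
        window_at(
            ins,
            upstream_exon_len + retained_len,
            INS6,
            "cryptic_junction",
            var_iso_pos if pos <= retained_len else None,
        ),
        window_at(ret, upstream_exon_len, RETENTION, "retention_5p", var_iso_pos),
        window_at(ret, upstream_exon_len + intron_len, RETENTION, "retention_3p", var_iso_pos),
    ]

    isoforms = {WT: canonical, INS6: ins, RETENTION: ret}
    for sig in sigs:
        for cat, iso in isoforms.items():
            if cat == sig.category:
                continue
            if _min_hamming(sig.anchor, iso) <= params.max_mismatches:
                raise ClassifierError(
                    f"signature {sig.name} is not distinguishable from the {cat} isoform "
                    f"at min_overhang={mo}; increase min_overhang"
                )
    return sigs


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), len(seqs[0])
    )


def _min_hamming(needle: str, haystack: str) -> int:
    if len(needle) > len(haystack):
        return len(needle)
    h = np.frombuffer(haystack.encode("ascii"), dtype=np.uint8)
    nd = np.frombuffer(needle.encode("ascii"), dtype=np.uint8)
    wins = sliding_window_view(h, len(needle))
    return int((wins != nd).sum(axis=1).min())


_SIG_CATEGORY_COLS = (WT, INS6, RETENTION)
_CHUNK = 8192


def classify_reads(
    ids: Sequence[str],
    seqs: Sequence[str],
    signatures: Sequence[JunctionSignature],
    params: ClassifierParams = ClassifierParams(),
    variant: CVariant | None = None,
) -> pd.DataFrame:
    """Classify reads; returns a frame with read_id, category, mismatches, allele.

    ``mismatches`` is -1 for AMBIGUOUS reads (no signature matched).  When
    ``variant`` is given, the base implied at the variant's isoform
    position is called as ref/alt/other for reads whose matched signature
    places that position within the read.
    """
    w = params.window
    rows_cat: list[np.ndarray] = []
    rows_mm: list[np.ndarray] = []
    rows_allele: list[list[str]] = []

    # group reads by length so each chunk is a dense matrix
    order = np.argsort([len(s) for s in seqs], kind="stable")
    out_cat = np.empty(len(seqs), dtype=object)
    out_mm = np.empty(len(seqs), dtype=np.int64)
    out_allele = np.empty(len(seqs), dtype=object)

    sig_arrs = [np.frombuffer(s.anchor.encode("ascii"), dtype=np.uint8) for s in signatures]
    big = 10**6

    pos = 0
    while pos < len(order):
        length = len(seqs[order[pos]])
        end = pos
        while end < len(order) and len(seqs[order[end]]) == length:
            end += 1
        for cstart in range(pos, end, _CHUNK):
            chunk_idx = order[cstart : min(cstart + _CHUNK, end)]
            chunk = [seqs[i] for i in chunk_idx]
            if length < w:
                raise ClassifierError(
                    f"read length {length} shorter than signature window {w}"
                )
            A = _encode(chunk)
            wins = sliding_window_view(A, w, axis=1)  # (n, P, w)
            n = len(chunk)
            dmin = np.empty((n, len(signatures)), dtype=np.int64)
            jmin = np.empty((n, len(signatures)), dtype=np.int64)
            for k, sa in enumerate(sig_arrs):
                d = (wins != sa).sum(axis=2)
                jmin[:, k] = d.argmin(axis=1)
                dmin[:, k] = d[np.arange(n), jmin[:, k]]
            matched = dmin <= params.max_mismatches
            cat_matched = {
                cat: np.any(
                    matched[:, [k for k, s in enumerate(signatures) if s.category == cat]],
                    axis=1,
                )
                for cat in _SIG_CATEGORY_COLS
            }
            ncat = sum(m.astype(int) for m in cat_matched.values())
            best = np.where(matched, dmin, big).argmin(axis=1)
            best_d = np.where(matched, dmin, big).min(axis=1)

            for r in range(n):
                gi = chunk_idx[r]
                if ncat[r] == 0:
                    out_cat[gi] = AMBIGUOUS
                    out_mm[gi] = -1
                    out_allele[gi] = ALLELE_NOT_COVERED
                    continue
                if ncat[r] >= 2:
                    out_cat[gi] = CONFLICT
                    out_mm[gi] = int(best_d[r])
                    out_allele[gi] = ALLELE_NOT_COVERED
                    continue
                k = int(best[r])
                sig = signatures[k]
                out_cat[gi] = sig.category
                out_mm[gi] = int(dmin[r, k])
                allele = ALLELE_NOT_COVERED
                if variant is not None and sig.variant_pos is not None:
                    iso_start = sig.window_start - int(jmin[r, k])
                    off = sig.variant_pos - iso_start
                    if 0 <= off < length:
                        base = chunk[r][off]
                        if base == variant.alt:
                            allele = ALLELE_ALT
                        elif base == variant.ref:
                            allele = ALLELE_REF
                        else:
                            allele = ALLELE_OTHER
                out_allele[gi] = allele
        pos = end

    return pd.DataFrame(
        {
            "read_id": list(ids),
            "category": out_cat,
            "mismatches": out_mm,
            "allele": out_allele,
        }
    )


def classify_read(
    seq: str,
    signatures: Sequence[JunctionSignature],
    params: ClassifierParams = ClassifierParams(),
    variant: CVariant | None = None,
    read_id: str = "read",
) -> ClassifiedRead:
    df = classify_reads([read_id], [seq], signatures, params, variant)
    row = df.iloc[0]
    return ClassifiedRead(row.read_id, row.category, int(row.mismatches), row.allele)


def count_categories(assignments: pd.DataFrame) -> dict[str, int]:
    counts = {cat: 0 for cat in CATEGORIES}
    counts.update(assignments["category"].value_counts().to_dict())
    return counts


def classify_readset(
    fastq_path,
    signatures: Sequence[JunctionSignature],
    params: ClassifierParams = ClassifierParams(),
    variant: CVariant | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Classify a FASTQ file; returns (category counts, per-read table)."""
    ids: list[str] = []
    seqs: list[str] = []
    record_no = 0
    try:
        for rec in SeqIO.parse(str(fastq_path), "fastq"):
            record_no += 1
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
    except ValueError as exc:
        raise ClassifierError(f"malformed FASTQ near record {record_no + 1}: {exc}") from exc
    if not ids:
        return {cat: 0 for cat in CATEGORIES}, pd.DataFrame(
            columns=["read_id", "category", "mismatches", "allele"]
        )
    df = classify_reads(ids, seqs, signatures, params, variant)
    return count_categories(df), df


# -- fragment-model geometry --------------------------------------------------


def category_windows(
    signatures: Iterable[JunctionSignature], category: str
) -> list[tuple[int, int, int]]:
    """(window_start, window_end_exclusive, isoform_len) per signature of a category."""
    return [
        (s.window_start, s.window_start + len(s.anchor), s.isoform_len)
        for s in signatures
        if s.category == category
    ]


def informative_start_count(iso_len: int, read_len: int, windows) -> int:
    """Number of uniform start positions whose read fully contains >= 1 window."""
    n_starts = iso_len - read_len + 1
    if n_starts <= 0:
        return 0
    intervals = []
    for a, b, _ in windows:  # read [s, s+R) contains [a, b) iff s <= a and b <= s+R
        lo = max(0, b - read_len)
        hi = min(a, n_starts - 1)
        if lo <= hi:
            intervals.append((lo, hi))
    intervals.sort()
    total = 0
    cur_lo, cur_hi = None, None
    for lo, hi in intervals:
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi + 1:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo + 1
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        total += cur_hi - cur_lo + 1
    return total


def informative_probability(
    signatures: Sequence[JunctionSignature], category: str, read_len: int
) -> float:
    """P(read covers a diagnostic window | isoform category), uniform starts."""
    windows = category_windows(signatures, category)
    if not windows:
        return 0.0
    iso_len = windows[0][2]
    n_starts = iso_len - read_len + 1
    if n_starts <= 0:
        return 0.0
    return informative_start_count(iso_len, read_len, windows) / n_starts


def expected_classified_proportions(
    signatures: Sequence[JunctionSignature],
    read_len: int,
    read_proportions: Mapping[str, float],
) -> dict[str, float]:
    """Classified-scale category proportions implied by read-level proportions.

    Under the uniform-start fragment model each category c contributes
    informative reads at rate pi_c * P(informative | c); conditioning on a
    read being classified gives the normalized product.
    """
    unnorm = {
        cat: read_proportions.get(cat, 0.0) * informative_probability(signatures, cat, read_len)
        for cat in ISOFORM_CATEGORIES
    }
    z = sum(unnorm.values())
    if z == 0:
        raise ClassifierError("no category has informative probability > 0")
    return {cat: v / z for cat, v in unnorm.items()}


def corrected_read_proportions(
    signatures: Sequence[JunctionSignature],
    read_len: int,
    counts: Mapping[str, int],
) -> dict[str, float]:
    """Coverage-corrected read-level proportion estimates from classified counts.

    Inverts the informative-probability weighting (effective-length style
    correction): pi_hat_c proportional to count_c / P(informative | c).
    """
    unnorm = {}
    for cat in ISOFORM_CATEGORIES:
        p = informative_probability(signatures, cat, read_len)
        unnorm[cat] = counts.get(cat, 0) / p if p > 0 else 0.0
    z = sum(unnorm.values())
    if z == 0:
        raise ClassifierError("no classified reads to correct")
    return {cat: v / z for cat, v in unnorm.items()}
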