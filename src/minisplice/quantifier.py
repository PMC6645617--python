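"""Isoform abundance summaries: percentages, Wilson intervals, phasing.

Percentages use half-up rounding to two decimals over the classified-read
denominator (WT + INS6 + RETENTION); AMBIGUOUS and CONFLICT reads are
reported but excluded.  The wild-type percentage is reported both rounded
directly and as the complement of the rounded aberrant percentages — the
two can legitimately differ in the last digit, and the complement is what
a summary that rounds the aberrant classes first would print.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import classifier as clf


class QuantError(ValueError):
    pass


def round_half_up_pct(count: int, total: int) -> float:
    """100*count/total rounded half-up to two decimals, exactly."""
    pct = Decimal(count * 100) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def classified_total(counts: Mapping[str, int]) -> int:
    return sum(int(counts.get(cat, 0)) for cat in clf.ISOFORM_CATEGORIES)


def percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Per-category rounded percentages plus the wild-type complement.

    ``wt_complement_pct`` is 100 minus the rounded aberrant percentages;
    ``WT`` is the directly rounded wild-type percentage.
    """
    total = classified_total(counts)
    if total == 0:
        raise QuantError("no classified reads to quantify")
    out = {
        cat: round_half_up_pct(int(counts.get(cat, 0)), total)
        for cat in clf.ISOFORM_CATEGORIES
    }
    aberrant = sum(out[cat] for cat in (clf.INS6, clf.RETENTION))
    out["wt_complement_pct"] = float(
        (Decimal(100) - Decimal(str(aberrant))).quantize(Decimal("0.01"))
    )
    return out


def wilson_ci(count: int, total: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if total <= 0 or not 0 <= count <= total:
        raise QuantError(f"invalid counts for interval: {count}/{total}")
    lo, hi = proportion_confint(count, total, alpha=1.0 - level, method="wilson")
    # exact boundary behavior: the Wilson interval has lo = 0 at count 0 and
    # hi = 1 at count == total; clear floating-point residue
    lo = 0.0 if count == 0 else max(float(lo), 0.0)
    hi = 1.0 if count == total else min(float(hi), 1.0)
    return lo, hi


def phase_retention(per_read: pd.DataFrame) -> float | None:
    """Fraction of allele-called retention reads carrying the alt base.

    Returns None (undefined) when no retention read has an allele call,
    rather than conflating "no evidence" with "no mutant reads".
    """
    ret = per_read[per_read["category"] == clf.RETENTION]
    called = ret[ret["allele"].isin([clf.ALLELE_REF, clf.ALLELE_ALT])]
    if len(called) == 0:
        return None
    return float((called["allele"] == clf.ALLELE_ALT).mean())


def het_check(wt_fraction: float) -> tuple[bool, str]:
    """Heterozygote-consistency flag: wild-type fraction >= 0.5.

    For a heterozygous carrier at least half of the transcripts are
    expected to be wild type; an excess above 0.5 is consistent with
    leaky wild-type splicing from the mutant allele and/or degradation of
    the PTC-bearing mutant transcripts by nonsense-mediated decay.
    """
    if not 0 <= wt_fraction <= 1:
        raise QuantError("wt_fraction must lie in [0, 1]")
    ok = wt_fraction >= 0.5
    if wt_fraction > 0.5:
        note = (
            f"wild-type fraction {wt_fraction:.4f} exceeds the 0.5 heterozygote "
            "minimum; consistent with leaky wild-type transcription from the "
            "mutant allele and/or nonsense-mediated decay of the mutant transcripts"
        )
    elif ok:
        note = "wild-type fraction equals the 0.5 heterozygote minimum"
    else:
        note = (
            f"wild-type fraction {wt_fraction:.4f} is below the 0.5 minimum "
            "expected for a heterozygous carrier"
        )
    return ok, note


@dataclass
class QuantReport:
    counts: dict[str, int]
    classified: int
    fractions: dict[str, float]
    percentages: dict[str, float]
    wilson: dict[str, tuple[float, float]]
    wt_complement_pct: float
    retention_phase_fraction: float | None
    het_consistent: bool
    het_narrative: str
    nmd_flags: dict[str, bool] = field(default_factory=dict)
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "classified": self.classified,
            "fractions": self.fractions,
            "percentages": self.percentages,
            "wilson_ci": {k: list(v) for k, v in self.wilson.items()},
            "wt_complement_pct": self.wt_complement_pct,
            "retention_phase_fraction": self.retention_phase_fraction,
            "het_consistent": self.het_consistent,
            "het_narrative": self.het_narrative,
            "nmd_flags": self.nmd_flags,
            "ci_level": self.level,
        }


def build_report(
    counts: Mapping[str, int],
    per_read: pd.DataFrame | None = None,
    nmd_flags: Mapping[str, bool] | None = None,
    level: float = 0.95,
) -> QuantReport:
    """Assemble the summary report from counts and per-read assignments."""
    total = classified_total(counts)
    if total == 0:
        raise QuantError("no classified reads to quantify")
    pcts = percentages(counts)
    fractions = {
        cat: int(counts.get(cat, 0)) / total for cat in clf.ISOFORM_CATEGORIES
    }
    wilson = {
        cat: wilson_ci(int(counts.get(cat, 0)), total, level)
        for cat in clf.ISOFORM_CATEGORIES
    }
    phase = phase_retention(per_read) if per_read is not None else None
    ok, note = het_check(fractions[clf.WT])
    full_counts = {cat: int(counts.get(cat, 0)) for cat in clf.CATEGORIES}
    return QuantReport(
        counts=full_counts,
        classified=total,
        fractions=fractions,
        percentages={cat: pcts[cat] for cat in clf.ISOFORM_CATEGORIES},
        wilson=wilson,
        wt_complement_pct=pcts["wt_complement_pct"],
        retention_phase_fraction=phase,
        het_consistent=ok,
        het_narrative=note,
        nmd_flags=dict(nmd_flags or {}),
        level=level,
    )
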