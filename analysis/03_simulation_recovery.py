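#!/usr/bin/env python
"""Stochastic simulation: proportion recovery and interval calibration.

Simulates heterozygote amplicon read sets (20,000 reads, 0.1% error,
category proportions 0.5823 / 0.3275 / 0.0902), classifies them and
checks (a) that coverage-corrected estimates recover the configured
read-level proportions and (b) that per-category Wilson 95% intervals
on the classified scale cover their implied truth across replicates.

Finding: raw classified proportions are biased (isoforms differ in how
often a uniform-start read covers a diagnostic junction), the geometric
correction removes the bias, and Wilson intervals are well calibrated.
"""

import argparse
from pathlib import Path

import pandas as pd

from minisplice import FixtureConfig, ReadSetSpec, build_fixture, build_signatures, simulate_reads
from minisplice import classifier as clf
from minisplice import quantifier as quant
from minisplice.pipeline import stage_seed


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=20)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = FixtureConfig()
    gene = build_fixture(cfg)
    variant = cfg.variant
    params = clf.ClassifierParams()
    sigs = build_signatures(gene, variant, cfg.retained_len, params)

    base = ReadSetSpec(n=20000, seed=0)
    read_props = base.overall_proportions()
    truth_q = clf.expected_classified_proportions(sigs, base.read_len, read_props)
    print("configured read-level proportions:",
          {k: round(v, 4) for k, v in read_props.items()})
    print("implied classified-scale truth:  ",
          {k: round(v, 4) for k, v in truth_q.items()})

    rows = []
    covered = {cat: 0 for cat in clf.ISOFORM_CATEGORIES}
    for rep in range(args.replicates):
        spec = ReadSetSpec(n=base.n, seed=stage_seed(args.seed, f"rep{rep}"))
        rs = simulate_reads(gene, spec, variant, cfg.retained_len, params)
        df = clf.classify_reads(rs.ids, rs.seqs, sigs, params, variant)
        counts = clf.count_categories(df)
        total = sum(counts[c] for c in clf.ISOFORM_CATEGORIES)
        corrected = clf.corrected_read_proportions(sigs, base.read_len, counts)
        row = {"replicate": rep, "classified": total}
        for cat in clf.ISOFORM_CATEGORIES:
            lo, hi = quant.wilson_ci(counts[cat], total)
            row[f"{cat}_frac"] = counts[cat] / total
            row[f"{cat}_corrected"] = corrected[cat]
            row[f"{cat}_covered"] = lo <= truth_q[cat] <= hi
            covered[cat] += row[f"{cat}_covered"]
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "recovery_coverage.tsv", sep="\t", index=False)

    print(f"\nover {args.replicates} replicates:")
    for cat in clf.ISOFORM_CATEGORIES:
        print(f"  {cat:9s} mean corrected estimate "
              f"{table[f'{cat}_corrected'].mean():.4f} "
              f"(truth {read_props[cat]:.4f}); CI coverage "
              f"{covered[cat]}/{args.replicates}")
    print(f"table written to {args.outdir / 'recovery_coverage.tsv'}")


if __name__ == "__main__":
    main()
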