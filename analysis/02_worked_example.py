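#!/usr/bin/env python
"""Reproduce the worked-example isoform percentages from exact counts.

Builds an error-free read set with exactly 29,700 wild-type, 16,700
insertion and 4,600 retention reads (51,000 total), classifies every
read by junction signature, and quantifies.

Finding: the classifier recovers the input counts exactly, giving
32.75% (INS6), 9.02% (RETENTION) and a wild-type complement of 58.23%
(direct rounding of the wild-type count gives 58.24% — the two differ
legitimately in the final digit).
"""

import argparse
from pathlib import Path

from minisplice import RunConfig, run_all
from minisplice import classifier as clf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/worked_example"))
    args = ap.parse_args()

    summary = run_all(RunConfig(seed=args.seed, mode="exact"), args.outdir)
    q = summary["quant"]
    print(f"classified reads: {q['classified']}")
    for cat in (clf.WT, clf.INS6, clf.RETENTION):
        lo, hi = q["wilson_ci"][cat]
        print(f"  {cat:9s} {q['counts'][cat]:6d}  {q['percentages'][cat]:6.2f}%  "
              f"95% CI [{100 * lo:.2f}, {100 * hi:.2f}]")
    print(f"wild-type complement: {q['wt_complement_pct']:.2f}%")
    print(f"retention phase fraction: {q['retention_phase_fraction']}")
    print(f"heterozygote check: {q['het_narrative']}")
    print(f"artifacts in {args.outdir}/")


if __name__ == "__main__":
    main()
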