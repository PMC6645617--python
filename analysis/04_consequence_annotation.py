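#!/usr/bin/env python
"""Annotate the protein-level consequence of each fixture isoform.

Translates the canonical and both aberrant isoforms, locates the first
in-frame stop, and applies the 50-nt NMD heuristic.

Finding: both aberrant isoforms truncate at the same codon (747) even
though only the 6-nt insertion is frame-preserving — the first retained
intronic base completes the stop codon in both, so the two events
produce the same functionally null, NMD-flagged allele.
"""

import argparse
import json
from pathlib import Path

from minisplice import FixtureConfig, IsoformSpec, apply_variant, build_fixture
from minisplice import classifier as clf
from minisplice.consequence import annotate_isoform
from minisplice.gene_model import INTRON_RETENTION, cryptic_donor


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = FixtureConfig()
    gene = build_fixture(cfg)
    mutant = apply_variant(gene, cfg.variant)
    n = gene.n_introns

    calls = {
        "canonical": annotate_isoform(gene, IsoformSpec.all_canonical(n), "canonical"),
        clf.INS6: annotate_isoform(
            mutant, IsoformSpec.single(n, 0, cryptic_donor(cfg.retained_len)), clf.INS6
        ),
        clf.RETENTION: annotate_isoform(
            mutant, IsoformSpec.single(n, 0, INTRON_RETENTION), clf.RETENTION
        ),
    }
    out = {name: c.to_dict() for name, c in calls.items()}
    (args.outdir / "consequence.json").write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")

    for name, c in calls.items():
        ptc = f"PTC at codon {c.ptc.codon_number} ({c.ptc.codon})" if c.ptc else "no PTC"
        print(f"{name:9s} insert {c.inserted_len:3d} nt, "
              f"frame {'preserved' if c.frame_preserving else 'shifted  '}, {ptc}, "
              f"{c.protein_description}, NMD={c.nmd_predicted}")


if __name__ == "__main__":
    main()
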