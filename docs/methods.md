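# Methods

## The mini-gene and its coordinate system

The analysis models the amplified region of a transcript as a mini-gene:
an alternating run of exons and introns stored in transcript orientation
(the amplicon is cDNA-derived, so no reverse-strand handling exists).
Coding (`c.`-style) coordinates anchor the first base of the first
modeled exon; intronic bases are addressed as `c.<anchor>+n` from the
last base of the upstream exon (or `-n` from the first base of the
downstream exon for the 3' half of the intron, matching HGVS practice).
`resolve_position` and `position_to_coding` are mutual inverses over
every modeled base, which the suite verifies exhaustively.

The default fixture has exons of 120/80/90/110 nt and introns of
130/90/100 nt, coding anchor c.2121 and phase 2. These values are chosen
so the modeled coordinates reproduce the numbering of the motivating
variant: the first donor boundary falls at c.2240, the variant is
c.2240+5G>A, and the codon completed by the first retained intronic base
is codon 747. Constrained positions are pinned; all remaining sequence is
seeded-random filler (default fixture seed 2019, a fixed study condition):

* intron 16 begins `GTAAGG` (so +5 is G on the reference allele) and a
  near-consensus cryptic donor `GTAAGT` occupies intron positions +7..+12,
  i.e. the cryptic GT sits 7 bp downstream of the native donor and using
  it retains 6 nt;
* exon 16 ends `TA` and is in frame such that those two bases plus the
  first intronic base (G) form an in-frame TAG stop — hence both aberrant
  isoforms truncate at the same codon regardless of frame;
* exon 17 begins `CA`, keeping the straddling canonical codon (TAC, Tyr)
  stop-free and keeping junction signatures separable;
* all introns satisfy GT…AG, and in-frame stops are scrubbed from the
  canonical transcript so the only PTC is the one retained intronic
  sequence creates.

A "cryptic donor 7 bp downstream" is therefore represented as
`retained_len = 6` with the reported offset defined as the 1-based intron
position of the first base of the cryptic GT (`retained_len + 1`).

## Read simulation

Reads are single-end, default 150 nt, with uniform start positions over
each isoform, constant Q37 quality strings (classification ignores
qualities) and substitution-only errors at a uniform default rate of
10⁻³ per base — substitutions only, so the classifier's mismatch
tolerance stays interpretable. The heterozygote model draws each read's
allele (mutant fraction 0.5), then its isoform: the wild-type allele is
always canonical; the mutant allele defaults to 16.46% canonical, 65.5%
cryptic and 18.04% retention, making the overall read-level category
proportions (0.5823, 0.3275, 0.0902) — the classified abundances the
assay reports. Every read carries a truth record (allele, isoform,
whether it fully contains a diagnostic junction window, whether it
covers the variant base). Seeds are mandatory; a run seed fans out to
per-stage substreams keyed by stage name, so identical config + seed
gives byte-identical outputs.

What the simulator does *not* emulate: paired ends, indels, quality-
dependent errors, PCR duplicates and, notably, amplification-efficiency
differences between isoforms of different lengths — a real RT-PCR
amplicon pool may over- or under-represent the longer retention product,
so passing tests here validate the informatics, not the absence of
amplification bias in real data.

## Classification

The isoform set is closed, so spliced alignment is unnecessary: each
isoform is diagnosed by a 16-nt signature (2 × `min_overhang` = 8)
centered on its diagnostic junction — the wild-type exon16|exon17
junction, the cryptic junction after the 6 retained nt, and the 5' and 3'
boundaries of the retained intron (either suffices for RETENTION). A
read is assigned to the unique category whose signature occurs in it with
at most `max_mismatches = 1` substitutions under exact sliding-window
Hamming comparison. Reads containing no full signature window are
AMBIGUOUS (they lie entirely in sequence shared by all isoforms); reads
matching two distinct categories — including equal-mismatch ties — are
CONFLICT. Signature construction verifies distinguishability: if any
signature occurs within tolerance in another category's isoform, it
aborts and demands a larger overhang. Aberrant-isoform signatures are
built on the mutant allele (their retained sequence contains the variant
base); the implied gapless alignment of a matched read also reads off the
base over intron position +5, phasing INS6 and retention reads to an
allele (`ref`/`alt`/`other` for an error base/`not_covered`).

## Quantification and calibration

Percentages are computed over classified reads (WT + INS6 + RETENTION;
AMBIGUOUS and CONFLICT are reported but excluded) and rounded half-up to
two decimals. The wild-type figure is reported twice: rounded directly,
and as 100 minus the rounded aberrant percentages; with the worked-example
counts these give 58.24% and 58.23% respectively, and both appear in the
report because summaries in the field are often computed the second way.
Wilson score intervals (not Wald) are used for stability at small counts.

Under uniform read starts, the probability that a read fully contains a
diagnostic window differs by category (isoform lengths differ and
retention has two windows): about 0.450 (WT), 0.463 (INS6) and 0.638
(RETENTION) at 150-nt reads. Raw classified proportions therefore
estimate the *classified-scale* proportions, computable in closed form
from the fixture geometry; conditioned on the classified total, each
category count is exactly binomial on that scale, so Wilson coverage is
assessed against it (the calibration checks use 100 replicates of 20,000
reads). For read-level abundances the quantifier also reports
coverage-corrected estimates (counts divided by their informative
probability, renormalized — an effective-length-style correction), which
recover the configured proportions without bias.

The heterozygote check flags wild-type fractions ≥ 0.5; an excess above
0.5 is annotated as consistent with leaky wild-type splicing from the
mutant allele and/or NMD-shortened half-life of the PTC-bearing
transcripts. The retention phase fraction is the share of allele-called
retention reads carrying the alternate base; it is reported as undefined
(not zero) when no retention read covers the variant.

## Donor scoring

The PWM is a transparent stand-in for external splice-site predictors: a
9-position (−3..−1 exonic, +1..+6 intronic) log₂-odds matrix versus a
uniform 0.25 background, built from a bundled table of human donor-site
base frequencies (consensus (C/A)AG|GTRAGT) with pseudo-count 10⁻³ so
the obligate GT positions stay finite for non-GT bases. Scores are in
bits; only directions and rankings are interpreted. "Abolish/weaken" is
operationalized as delta < 0 with the mutant site below a configurable
0-bit use threshold. On the default fixture the native donor scores
5.93 bits (reference) versus 2.14 bits (+5 A), delta −3.79 bits, while
the cryptic site at +7 scores 12.81 bits on either allele — the scan
ranks it first by a wide margin. No attempt is made to reproduce any
named external tool's numeric scores.

## Consequence annotation

Each mature mRNA is translated from the declared frame; the first
in-frame stop is the PTC. Codon numbers add the transcript-wide offset
implied by the coding anchor (first complete modeled codon = 708), and
the description renders the canonical transcript's residue at that codon,
e.g. `p.Tyr747*` on the fixture (the index is the modeled quantity; the
residue identity is fixture sequence, not a claim about any real
transcript). NMD is predicted by the standard heuristic: PTC more than
50 nt (configurable) upstream of the last exon–exon junction, with
junction positions taken from the splice map — note a retained intron
contributes no junction. Both aberrant fixture isoforms are NMD-positive;
a PTC in the last exon is not.

## Numerical and design choices

* Exact sliding-window comparison over alignment: bit-reproducible, no
  external aligner, adequate because the isoform set is closed; the cost
  is no tolerance to indel sequencing errors (not simulated) and no
  discovery of unanticipated isoforms.
* A read matching both retention signatures counts once as RETENTION;
  CONFLICT is reserved for cross-category evidence.
* Rounding is half-up (`Decimal`), not banker's, to match the reporting
  convention of the summary percentages.
* Wilson bounds are clamped exactly to 0 at zero counts and 1 at full
  counts.
* Problem sizes in the test-suite and acceptance runs — 51,000-read
  worked example, 5,000-read oracle checks, 100 × 20,000-read calibration
  replicates — are the package's chosen desk-scale defaults; the whole
  suite runs in about a minute on one CPU.

## Known limitations

* Single-variant, single-aberrant-intron model; multi-intron aberrations
  are rejected rather than supported.
* No paired-end, indel, duplicate or amplification-bias modeling (see
  above); fragment starts are uniform, which real libraries are not.
* The PWM is first-order (no dependencies between positions), unlike
  maximum-entropy or neural splice models.
* Protein descriptions are HGVS-flavored, not a full HGVS implementation
  (no `ins`/`fs` nomenclature); codon numbering beyond the modeled region
  is presentation derived from the coding anchor.
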