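# Methods

`typhamir` re-implements, as a tested library, the standard
transcriptome-based workflow for cataloguing miRNAs in a plant without a
sequenced genome and calling their response to a treatment from two
unreplicated small-RNA libraries (a control, "CK", and a cadmium-treated
library, "Cd"). This note records the models, the parameters that
matter, and the design decisions taken where the workflow leaves choices
open.

## Read cleaning and tag collapsing

Raw reads pass five filters in a fixed order, and each removed read is
counted once under its first failing rule so raw = clean + Σ removed
holds exactly: (1) quality — more than 10% of bases below Phred 20, or
any N; (2) 5' contaminant — the first 8 nt match the last 8 nt of the 5'
adapter with at most one mismatch; (3) 3'-adapter trimming — the insert
is everything upstream of the left-most match of the adapter's first
8 nt, falling back to a ≥ 6 nt adapter prefix at the read end; reads
with no recognizable adapter are discarded, because the insert boundary
is unknowable in this library layout, and an empty insert marks
adapter–adapter ligation; (4) poly(A) — ≥ 80% A or a terminal run of
eight A; (5) length — inserts outside 15–30 nt are dropped. Cleaned
inserts are collapsed to unique tags with per-library counts, ordered by
descending total count with lexicographic tie-breaks so all downstream
output is deterministic. Internally everything is DNA alphabet (T);
reports render U.

## Annotation priority

Each unique tag receives exactly one category by exact sense-strand
substring matching, in the priority order ncRNA (GenBank consulted
before Rfam; within a source rRNA > tRNA > snRNA > snoRNA, the
conventional listing order) > known miRNA > other reference >
unannotated. Sense-only matching reflects the directionality of
adapter-ligated small-RNA reads; exact matching mirrors the
perfect-match mapping used throughout. Genome-dependent classes
(repeat/exon/intron) are collapsed into a single optional
"other reference" category because no genome exists for the organism
this workflow is aimed at.

## RNA folding energy model

Hairpin prediction and hybrid energies use a nearest-neighbor free-energy
model authored in this package: Turner-style Watson–Crick pair-stack
ΔG°37 values; a simplified two-level wobble term (−1.2 kcal/mol for a
stack containing one G:U pair, −0.5 for two) in place of the full wobble
table; size-dependent hairpin/bulge/internal-loop initiation penalties
with 1.75·RT logarithmic extrapolation and a capped asymmetry penalty;
and a linear multiloop cost a + b·(branches + 1) with a = 3.4,
b = 0.4 kcal/mol and free unpaired bases. Terminal-pair (AU/GU end) and
dangling-end bonuses are omitted. All arithmetic is integer
centi-kcal/mol, so the Zuker-style dynamic program, the independent
loop-decomposition evaluator, and brute-force enumeration of structures
agree exactly — that exactness is what the fold-oracle tests assert.
Minimum hairpin loop is 3 nt; bulge/internal loops are capped at 30
unpaired bases; tie-breaks take the first minimal option in a fixed
enumeration order, so folding is fully deterministic. Every precursor
criterion used downstream depends only on the *ranking* of energies, not
their absolute calibration; a test cross-checks that the model's MFEs
correlate strongly with RNAfold's across hairpins and random sequences.

The duplex (miRNA:target hybrid) energy uses the same tables with pairs
advancing 5'→3' on one strand and 3'→5' on the other, no intramolecular
pairs, no initiation penalty, and a 15-nt loop cap; it is likewise
checked against exhaustive duplex enumeration.

## miRNA identification

**Conserved.** A tag matches a known mature miRNA when their lengths
differ by at most 2 nt and the Hamming distance over the best ungapped
sliding alignment is ≤ 2 (substitution-only, the convention behind
"within two mismatches" in tag-based pipelines). Per reference, matched
tags form a cluster; the dominant-count member (ties: lexicographically
smallest) is the representative and expression is the summed counts of
members passing the 2-mismatch rule.

**Novel.** Tags of 18–26 nt with total count ≥ 3 that map perfectly to
the transcriptome — and were not already classified as ncRNA, known
miRNA, or conserved-cluster members — seed hairpin searches. Around each
hit two windows are cut ([pos − flank, end + 20) and
[pos − 20, end + flank), flank default 150 nt), folded in both
orientations, trimmed to the outermost base pair enclosing the mature,
re-folded, and accepted when: the mature lies wholly on one arm, has
≥ 16 paired bases, ≤ 4 unpaired with ≤ 2 consecutive, the precursor is
68–300 nt with MFE ≤ −18 kcal/mol and MFEI ≤ −0.5
(MFEI = (MFE/length×100)/GC%). These thresholds follow the common
plant-miRNA (Mireap-style) convention and are all config-exposed.
Overlapping candidate loci merge (sense orientation preferred, then
lower MFE), and a locus that coincides with a conserved miRNA's
precursor is reported as that precursor's opposite arm rather than as a
new miRNA. Novel expression sums cluster members whose differences from
the representative are confined to the outermost 3 nt of each end
(trims/extensions counted per nucleotide), middle exact, ≤ 3 in total.

**5p/3p pairs and isomiRs.** A record is flagged higher-confidence when
a second expressed tag occupies the opposite arm at the position
predicted by Dicer duplex geometry (2-nt 3' overhangs, ±1 nt
tolerance). IsomiRs are all tags aligning to the precursor that overlap
the mature span by ≥ 50% of the mature length, with signed end offsets
(positive = trimmed, negative = extended).

## Target prediction

A site is scored by pairing miRNA position i against window position
L − 1 − i: mismatch 1.0, G:U wobble 0.5, gap 2.0 (at most one gap,
allowing windows one nucleotide shorter or longer than the miRNA), with
penalties doubled at miRNA positions 2–13 — the psRNATarget-style scheme
for plant miRNAs, whose targets are near-perfectly complementary. The
expectation is the penalty sum; windows at or below the cutoff (default
3.0) are reported, overlapping windows reduced to the best scorer, each
with its hybrid duplex MFE and a three-row alignment ("o" = wobble,
"x" = mismatch). The transcript scan is vectorized (per-gap prefix-sum
decomposition), and every reported site's score is identical to the
reference single-window scorer. Seed span and all penalties are
configurable; scanning is sense-strand only (miRNAs pair with mRNA).

## Differential expression

Per-miRNA counts (conserved + novel expression sums) are normalized to
transcripts-per-million over the total miRNA-matched reads of each
library. Fold change is log2(Cd/CK) on TPM with a 0.01-TPM floor so
library-specific miRNAs remain finite and plottable. Significance uses
the Audic–Claverie posterior predictive for two unreplicated tag-count
libraries: p(y|x) = r^y (x+y)! / (x! y! (1+r)^{x+y+1}) with r = N2/N1,
which is the negative-binomial pmf NB(x+1, 1/(1+r)); tails are computed
through scipy's nbinom (log-gamma internals, safe to counts ≥ 10^6) and
the two-sided p doubles the smaller inclusive tail, capped at 1. A
miRNA is called significant at p < 0.05 *and* |fold| ≥ 1.5, starred at
0.05/0.01; a library-swap changes this p only by the observed point's
probability mass (the inclusive tails both contain it), which the
symmetry test accounts for analytically. No multiple-testing correction
enters the calls — single-library digital expression conventionally
reports raw p — but a Benjamini–Hochberg column is emitted for
reference. Library-specific flags (CK_only/Cd_only) require only a zero
count on one side. Calibration: under an equal-Poisson null the
empirical type-I error at 0.05 is 0.04–0.055 across means 20–200;
4-fold changes at mean ≥ 50 are detected essentially always. With
genuine overdispersion between libraries the test is anticonservative —
the price of an unreplicated design, inherited by any analysis built on
it.

## Synthetic data: what it emulates, and what it does not

The generator plants hairpin precursors (stem 30–45 nt + loop 8–20 nt +
reverse-complement stem, 0–2 single-nucleotide bulges in the arm
opposite the mature, GC-biased stems, total 68–255 nt), each carrying a
20–22 nt mature with a 70% 5'-U bias. Defaults mirror the emulated
study's qualitative structure: 12 conserved + 8 novel miRNAs; four
conserved miRNAs down-regulated 1.65× at mid abundance with the
dominant expressors stable; novel miRNAs lower-abundance with 5×
responses (two up, three down); and near-library-specific members
emulated with a 0.05-count mean on the silent side (means stay strictly
positive). Counts are negative-binomial (Poisson in the dispersion → 0
limit) with default dispersion 0.01, the scale of variation between
sequencing runs of one RNA pool; 20% of miRNA reads are isomiR variants
(1–3 nt terminal trims/extensions drawn from the precursor), 5% extra
reads come from the star arm, 30% of each library is ncRNA fragments
(matching the share annotated away in real libraries), 6% is
deliberately bad reads (no insert, poly(A), short, low-quality, 5'
contaminant), and the rest is uniform random background. Reads carry
the TruSeq 3' adapter and fixed 49-nt read geometry with Sanger
qualities. The transcriptome embeds precursors verbatim plus planted
target sites (perfect, single-wobble, single-mismatch patterns) with
TSV truth side-cars, so tests never re-derive the truth from FASTA.

What passing these tests shows: the pipeline recovers exactly what was
planted, conserves counts, and is bit-reproducible. What they cannot
show: robustness to real-data features the generator does not model —
sequencing-error profiles beyond uniform substitution, RNA-family
homology between background and references, biased base composition,
expression-dependent adapter artifacts, or genuine biological
replicate variance.

## Problem sizes and numerics

The default validation runs use libraries of 2×30,000–100,000 reads,
~70 unigenes, and 20 planted precursors; the acceptance script uses
2×50,000 reads and repeats the calibration with 2,000 replicate pairs.
These sizes put every recovery estimate's sampling error well inside
its tolerance while keeping a full run in tens of seconds. Folding is
O(n³) with a numba-jitted kernel and per-sequence memoization; windows
are ≤ ~200 nt. All pipeline outputs are written with fixed column
order, fixed float formatting and deterministic row sorts; re-running
with an identical config and seed is byte-identical, which the
acceptance suite checks at the file level.

## Known limitations

- The energy parameterization is deliberately simplified (no terminal
  mismatches, dangles, or special loops); absolute MFEs differ from
  Turner-2004 engines by a few kcal/mol on typical precursors.
- Conserved matching is substitution-only; a real indel isomiR beyond
  the 2-nt length allowance is counted as novel-eligible rather than as
  family evidence.
- Without replicates the Audic–Claverie calls quantify sampling noise
  only; biological variability is not separable from treatment effect.
- Perfect-match annotation cannot recognize diverged ncRNA fragments;
  in real data a family-level scan (e.g. covariance models) removes
  more of the library.
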