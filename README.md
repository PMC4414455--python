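# typhamir

Small RNA-seq analysis for plants without a sequenced genome: miRNA
identification against an assembled transcriptome, isomiR cataloguing,
miRNA-target prediction, and two-library differential expression. The
package grew out of the workflow used to profile cadmium-responsive
miRNAs in the cattail *Typha angustifolia* — a metal-hyperaccumulating
wetland plant — where a control (CK) and a Cd-treated (Cd) small-RNA
library are compared against a Trinity-style unigene set rather than a
genome.

It is intended for people building or validating tag-count small-RNA
pipelines: every stage is an importable, deterministic function, and a
ground-truthed synthetic-data generator makes the whole chain testable
end to end without downloads.

## What it computes

* **Cleaning and collapsing** — quality / 5'-contaminant / adapter /
  poly(A) / length filters with exact per-reason accounting, then
  unique tags with per-library counts, plus the length-distribution and
  5'-first-base summaries.
* **Annotation** — each tag gets exactly one category by exact
  sense-strand matching under the priority
  ncRNA (GenBank > Rfam) > known miRNA > other > unannotated.
* **Conserved miRNAs** — matching to known matures within 2
  substitutions (length ± 2 nt), clustering, dominant-read
  representatives, summed cluster expression.
* **Novel miRNAs** — transcript windows around perfectly mapped tags
  folded with a nearest-neighbor MFE model (integer-exact Zuker-style
  DP); precursors accepted on the plant criteria: mature on one arm,
  ≥ 16 bases paired (≤ 4 unpaired, ≤ 2 consecutive), 68–300 nt,
  MFE ≤ −18 kcal/mol, MFEI ≤ −0.5, where
  MFEI = (MFE/length × 100)/GC%. 5p/3p partners are detected from Dicer
  duplex geometry (2-nt 3' overhangs) and isomiRs enumerated with
  signed end offsets.
* **Targets** — psRNATarget-style expectation: mismatch 1.0, G:U wobble
  0.5, gap 2.0, doubled at miRNA positions 2–13; sites kept at
  expectation ≤ 3.0 with hybrid duplex MFEs.
* **Differential expression** — TPM over miRNA-matched totals,
  log2(Cd/CK), and the Audic–Claverie test
  p(y|x) = r^y (x+y)! / (x! y! (1+r)^{x+y+1}), r = N2/N1, two-sided by
  doubling the smaller tail; significant at p < 0.05 and fold ≥ 1.5,
  with CK_only/Cd_only flags.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

`examples/` holds one short script per capability. The full pipeline on
a simulated 2 × 20,000-read experiment
(`python examples/07_full_pipeline.py`) prints, among other rows:

```
              conserved_mirnas     12
                  novel_mirnas      8
         mirnas_with_precursor     20
              mirna_5p3p_pairs     20
            significant_mirnas     12

significant miRNAs (p < 0.05, fold change >= 1.5):
  kno-miR001     log2FC  -0.60 p 6.70e-05 **
  kno-miR005     log2FC +19.75 p 4.63e-22 ** [Cd_only]
  novel_mir_1    log2FC  +2.27 p 1.80e-55 **
  novel_mir_8    log2FC +19.46 p 3.73e-18 ** [Cd_only]
```

All 12 planted conserved and all 8 planted novel miRNAs are recovered,
each with a qualifying hairpin precursor and a detected opposite-arm
partner; the significant set consists of the planted Cd-responsive
members — modest (~1.65×) shifts among conserved miRNAs, strong (5×)
shifts among novel ones — plus the library-specific miRNAs flagged
`Cd_only`/`CK_only`. The ±19–20 log2 values are the 0.01-TPM floor at a
zero count, i.e. "detected in one library only", not a measured ratio.

The same run can be driven from the shell:

```bash
typhamir simulate --seed 1 --outdir sim --depth 20000
typhamir run-all --config cfg.yaml     # paths + thresholds, all echoed
typhamir report --outdir out
```

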