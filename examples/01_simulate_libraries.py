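"""Generate a ground-truthed two-library small-RNA experiment.

Plants conserved and novel pre-miRNA hairpins with condition-specific
abundances, adds ncRNA fragments, background and bad reads, and writes
FASTQ libraries, reference FASTAs and truth TSVs.
"""

import tempfile
from pathlib import Path

from typhamir import simulate

with tempfile.TemporaryDirectory() as tmp:
    data = simulate(seed=1, outdir=Path(tmp), depth=20_000)

    print(f"planted precursors : {len(data.truth.premirnas)}")
    n_cons = sum(p.conserved for p in data.truth.premirnas)
    print(f"  conserved / novel: {n_cons} / "
          f"{len(data.truth.premirnas) - n_cons}")
    print(f"reads per library  : {len(data.lib_ck.reads)} (CK), "
          f"{len(data.lib_cd.reads)} (Cd)")
    print(f"transcriptome      : {len(data.transcriptome)} unigenes")
    print(f"files written      : {sorted(p.name for p in data.paths.values())}")

    p = data.truth.premirnas[0]
    print(f"\nexample hairpin {p.name} ({len(p.sequence)} nt, "
          f"mature on the {p.arm} arm):")
    print(f"  mature: {p.mature}")
    ck, cd = data.truth.mirna_abundance[p.name]
    print(f"  mean abundance CK={ck:.0f}, Cd={cd:.0f} reads "
          f"(true log2 FC {data.truth.fold_changes[p.name]:+.2f})")

# The counts table is the ground truth a lossless pipeline should
# recover; the FASTQ files are what the pipeline actually sees.
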