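"""Fold a hairpin, predict a novel miRNA from a transcript, detect its
5p/3p partner and enumerate its isomiRs.
"""

import numpy as np

from typhamir import (NovelParams, detect_star, enumerate_isomirs,
                      fold_rna, mfei, predict_novel)
from typhamir.energy import gc_percent
from typhamir.preprocess import SmallRNATag
from typhamir.synthetic import gen_premirna, star_sequence

rng = np.random.default_rng(3)
pre = gen_premirna(stem_len=36, loop_len=10, n_bulges=1, rng=rng)
pre.name = "demo"

fold = fold_rna(pre.sequence)
print(f"precursor ({len(pre.sequence)} nt), MFE {fold.mfe:.2f} kcal/mol, "
      f"MFEI {mfei(fold.mfe, len(pre.sequence), gc_percent(pre.sequence)):.2f}")
print(pre.sequence)
print(fold.dotbracket)

# embed the precursor in a transcript and express the mature + star +
# one trimmed isomiR
flanks = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 250)])
          for _ in range(2)]
transcriptome = {"unigene_demo": flanks[0] + pre.sequence + flanks[1]}
star = star_sequence(pre)
tags = [SmallRNATag(pre.mature, 120, 40),
        SmallRNATag(pre.mature[1:], 15, 5),
        SmallRNATag(star, 6, 2)]

cands, records = predict_novel(tags, transcriptome, NovelParams())
rec = records[0]
print(f"\n{rec.name}: mature {rec.representative_seq} on the "
      f"{rec.precursor.arm} arm, expression CK={rec.expr_ck} "
      f"Cd={rec.expr_cd}")

partner = detect_star(rec.precursor, tags)
print(f"5p/3p partner strand: {partner}")

print("\nisomiRs (offsets: positive = trimmed, negative = extended):")
for iso in enumerate_isomirs(rec, tags):
    label = "canonical" if iso.is_canonical else "variant"
    print(f"  {iso.sequence}  5'{iso.offset_5p:+d} 3'{iso.offset_3p:+d} "
          f"CK={iso.count_ck} Cd={iso.count_cd} ({label})")
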