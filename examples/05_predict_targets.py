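"""Score miRNA target sites with the seed-weighted, G:U-aware
expectation and scan a small transcriptome.
"""

import numpy as np

from typhamir import duplex_mfe, scan_targets, score_site
from typhamir.io import revcomp
from typhamir.synthetic import build_target_site

rng = np.random.default_rng(5)
mirna = "TGACAGAAGAGAGTGAGCACA"

perfect = revcomp(mirna)
wobble = build_target_site(mirna, [(15, "gu")], rng)
seed_mm = build_target_site(mirna, [(5, "mm")], rng)

for label, site in (("perfect", perfect), ("G:U at position 15", wobble),
                    ("mismatch at position 5", seed_mm)):
    exp, aln = score_site(mirna, site)
    print(f"{label}: expectation {exp}")
    print(aln + "\n")

# plant the wobble site in a transcript and scan at cutoff 3.0
flank = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
tx = {"unigene_t": flank + wobble + flank[:300]}
sites = scan_targets("demo-miR", mirna, tx)
for s in sites:
    print(f"site on {s.unigene} at {s.span}: expectation "
          f"{s.expectation}, hybrid MFE {s.duplex_mfe:.1f} kcal/mol")
print(f"\nperfect-hybrid MFE: {duplex_mfe(mirna, perfect):.1f} kcal/mol")
# 'o' marks a G:U wobble (penalty 0.5, not a mismatch); 'x' marks a
# mismatch (1.0); penalties double inside miRNA positions 2-13.
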