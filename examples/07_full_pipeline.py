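"""Run the full pipeline end-to-end on a simulated experiment and print
the summary table plus the significant miRNAs.
"""

import tempfile
from pathlib import Path

from typhamir import PipelineConfig, run_pipeline, simulate

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    data = simulate(seed=1, outdir=tmp / "sim", depth=20_000)
    cfg = PipelineConfig(
        reads_ck=str(data.paths["reads_ck"]),
        reads_cd=str(data.paths["reads_cd"]),
        transcriptome=str(data.paths["transcriptome"]),
        mature_ref=str(data.paths["mature_ref"]),
        ncrna_genbank=str(data.paths["ncrna_genbank"]),
        ncrna_genbank_types=str(data.paths["ncrna_genbank_types"]),
        ncrna_rfam=str(data.paths["ncrna_rfam"]),
        ncrna_rfam_types=str(data.paths["ncrna_rfam_types"]),
        outdir=str(tmp / "run"))
    report = run_pipeline(cfg)

    print(report.summary.to_string(index=False))
    print("\nsignificant miRNAs (p < 0.05, fold change >= 1.5):")
    for r in report.diffexp:
        if r.sig_label:
            extra = f" [{r.specific}]" if r.specific else ""
            print(f"  {r.mirna:<14} log2FC {r.log2fc:+6.2f} "
                  f"p {r.pvalue:.2e} {r.sig_label}{extra}")
    print(f"\nreport files written to {report.outdir}")
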