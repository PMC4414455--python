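"""Two-library digital differential expression of miRNAs.

Counts are normalized to transcripts-per-million over the total number of
miRNA-matched reads in each library, fold change is log2(Cd/CK) with a
small TPM floor so library-specific miRNAs stay finite, and significance
comes from the Audic-Claverie Bayesian test for tag counts from two
libraries without replicates: given x counts in a library of N1 tags, the
posterior-predictive probability of y counts in a library of N2 tags is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y! (1+N2/N1)^(x+y+1))

which is the negative-binomial pmf NB(x+1, N1/(N1+N2)) evaluated at y;
tails are therefore computed with scipy's nbinom (overflow-safe via
log-gamma internally). The two-sided p doubles the smaller tail, capped
at 1; a miRNA is called significant at p < 0.05 and |fold change| >= 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, nbinom


@dataclass
class DiffExpResult:
    mirna: str
    count_ck: int
    count_cd: int
    tpm_ck: float
    tpm_cd: float
    log2fc: float
    pvalue: float
    sig_label: str = ""          # '', '*' or '**'
    specific: str = ""           # '', 'CK_only' or 'Cd_only'

    def validate(self) -> None:
        if not 0 <= self.pvalue <= 1:
            raise AssertionError("p-value outside [0, 1]")
        if self.sig_label == "**" and not self.pvalue < 0.01:
            raise AssertionError("** requires p < 0.01")
        if self.sig_label == "*" and not self.pvalue < 0.05:
            raise AssertionError("* requires p < 0.05")
        if (self.specific == "Cd_only") != \
                (self.count_ck == 0 and self.count_cd > 0):
            raise AssertionError("Cd_only flag inconsistent")


def tpm(count: float, library_total: float) -> float:
    """Transcripts per million: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return count / library_total * 1e6


def log2_fold_change(tpm_cd: float, tpm_ck: float,
                     floor: float = 0.01) -> float:
    """log2(Cd/CK) with zeros floored at `floor` TPM."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return float(np.log2(max(tpm_cd, floor) / max(tpm_ck, floor)))


def audic_claverie_p(x, N1, y, N2):
    """Two-sided Audic-Claverie p for observing y (library 2, N2 total)
    given x (library 1, N1 total). Vectorized over x and y."""
    x = np.asarray(x)
    y = np.asarray(y)
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    r = N2 / N1
    prob = 1.0 / (1.0 + r)
    lower = nbinom.cdf(y, x + 1, prob)          # P(k <= y | x)
    upper = nbinom.sf(y - 1, x + 1, prob)       # P(k >= y | x)
    p = 2.0 * np.minimum(lower, upper)
    return np.minimum(p, 1.0) if p.ndim else float(min(p, 1.0))


def call_de(records, totals: tuple[float, float],
            p_cut: float = 0.05, fc_cut: float = 1.5,
            floor: float = 0.01) -> list[DiffExpResult]:
    """Full differential-expression table for MatureMiRNARecord-like
    inputs (anything with .name, .expr_ck, .expr_cd).

    Significance requires p < p_cut AND |fold ratio| >= fc_cut; stars mark
    p < 0.05 (*) and p < 0.01 (**); library-specific flags are set when
    one library's count is zero.
    """
    total_ck, total_cd = totals
    out = []
    lfc_cut = float(np.log2(fc_cut))
    for rec in records:
        x, y = rec.expr_ck, rec.expr_cd
        t_ck = tpm(x, total_ck)
        t_cd = tpm(y, total_cd)
        lfc = log2_fold_change(t_cd, t_ck, floor)
        p = audic_claverie_p(x, total_ck, y, total_cd)
        sig = ""
        if p < p_cut and abs(lfc) >= lfc_cut:
            sig = "**" if p < 0.01 else "*"
        specific = ""
        if x == 0 and y > 0:
            specific = "Cd_only"
        elif y == 0 and x > 0:
            specific = "CK_only"
        res = DiffExpResult(mirna=rec.name, count_ck=x, count_cd=y,
                            tpm_ck=t_ck, tpm_cd=t_cd, log2fc=lfc,
                            pvalue=float(p), sig_label=sig,
                            specific=specific)
        res.validate()
        out.append(res)
    return out


def as_frame(results: list[DiffExpResult]) -> pd.DataFrame:
    """S14-style table with an informational Benjamini-Hochberg column
    (raw p thresholds drive the calls)."""
    df = pd.DataFrame([{
        "mirna": r.mirna, "count_ck": r.count_ck, "count_cd": r.count_cd,
        "tpm_ck": r.tpm_ck, "tpm_cd": r.tpm_cd, "log2fc": r.log2fc,
        "pvalue": r.pvalue, "sig_label": r.sig_label,
        "specific": r.specific} for r in results])
    if not df.empty:
        df["bh_fdr"] = false_discovery_control(df["pvalue"], method="bh")
    return df
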