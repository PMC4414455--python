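"""miRNA target prediction by G:U-aware complementarity scoring.

A site is scored by aligning the miRNA (5'->3') against the reverse
complement of a transcript window: each mismatch costs 1.0, each G:U
wobble 0.5 and each gap 2.0, with all penalties doubled inside the seed
(miRNA positions 2-13, 1-based from the 5' end); the expectation is the
penalty sum and sites at or below the cutoff (default 3.0) are reported,
reduced to the best-scoring window per overlapping locus. This is the
psRNATarget-style scheme used for plant miRNAs, where targets are near
perfectly complementary. Reported sites also carry the hybrid duplex MFE
under the same nearest-neighbor model as the hairpin folder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import _ENC
from .fold import duplex_mfe
from .io import revcomp, to_rna


@dataclass
class ScoringParams:
    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    seed_start: int = 2          # 1-based miRNA positions, inclusive
    seed_end: int = 13
    seed_factor: float = 2.0
    cutoff: float = 3.0
    max_gaps: int = 1


@dataclass
class TargetSite:
    mirna: str
    unigene: str
    span: tuple[int, int]        # 0-based half-open on the transcript
    alignment: str               # three rows: miRNA 5'->3' / symbols /
    expectation: float           # target 3'->5'
    duplex_mfe: float


# penalty class per (miRNA base, target base): 0 = pair, 1 = wobble,
# 2 = mismatch  (DNA alphabet, T == U)
_PAIR_CLASS = np.full((4, 4), 2, dtype=np.int64)
for a, b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PAIR_CLASS[_ENC[a], _ENC[b]] = 0
_PAIR_CLASS[_ENC["G"], _ENC["T"]] = 1
_PAIR_CLASS[_ENC["T"], _ENC["G"]] = 1

_SYMBOL = {0: "|", 1: "o", 2: "x"}


def _weights(L: int, p: ScoringParams) -> np.ndarray:
    w = np.ones(L)
    w[p.seed_start - 1:p.seed_end] = p.seed_factor
    return w


def _pos_weight(pos0: int, p: ScoringParams) -> float:
    return p.seed_factor if p.seed_start - 1 <= pos0 <= p.seed_end - 1 \
        else 1.0


def score_site(mirna: str, window: str,
               params: ScoringParams | None = None):
    """Expectation score and alignment of one miRNA against one window.

    The window length may equal the miRNA length (ungapped), exceed it by
    one (target bulge = gap in the miRNA row) or fall short by one (gap in
    the target row). Returns (expectation, alignment string).
    """
    p = params or ScoringParams()
    L = len(mirna)
    # miRNA position i pairs window position (len - 1 - i): reverse the
    # window so aligned characters face their pairing partners
    t = window[::-1]
    n = len(t)
    penalty_of = {0: 0.0, 1: p.wobble, 2: p.mismatch}

    def pair_class(mb: str, tb: str) -> int:
        return int(_PAIR_CLASS[_ENC[mb], _ENC[tb]])

    best = None
    if n == L:
        gaps = [None]
    elif n == L + 1:
        gaps = [("mirna", g) for g in range(L + 1)]
    elif n == L - 1:
        gaps = [("target", g) for g in range(L)]
    else:
        raise ValueError("window length must be miRNA length - 1 .. + 1")
    for gap in gaps:
        score = 0.0
        rows_m, rows_s, rows_t = [], [], []
        if gap is None:
            for i in range(L):
                c = pair_class(mirna[i], t[i])
                score += penalty_of[c] * _pos_weight(i, p)
                rows_m.append(mirna[i])
                rows_s.append(_SYMBOL[c])
                rows_t.append(t[i])
        elif gap[0] == "mirna":
            g = gap[1]
            score += p.gap * _pos_weight(min(g, L - 1), p)
            ti = 0
            for i in range(L + 1):
                if i == g:
                    rows_m.append("-")
                    rows_s.append(" ")
                    rows_t.append(t[ti])
                    ti += 1
                    continue
                mi = i if i < g else i - 1
                c = pair_class(mirna[mi], t[ti])
                score += penalty_of[c] * _pos_weight(mi, p)
                rows_m.append(mirna[mi])
                rows_s.append(_SYMBOL[c])
                rows_t.append(t[ti])
                ti += 1
        else:
            g = gap[1]
            score += p.gap * _pos_weight(g, p)
            ti = 0
            for i in range(L):
                if i == g:
                    rows_m.append(mirna[i])
                    rows_s.append(" ")
                    rows_t.append("-")
                    continue
                c = pair_class(mirna[i], t[ti])
                score += penalty_of[c] * _pos_weight(i, p)
                rows_m.append(mirna[i])
                rows_s.append(_SYMBOL[c])
                rows_t.append(t[ti])
                ti += 1
        if best is None or score < best[0]:
            lines = ("miRNA  5' " + to_rna("".join(rows_m)) + " 3'",
                     "          " + "".join(rows_s),
                     "target 3' " + to_rna("".join(rows_t)) + " 5'")
            width = max(len(x) for x in lines)
            best = (score, "\n".join(x.ljust(width) for x in lines))
    return best


def _scan_ungapped(mcodes: np.ndarray, tcodes: np.ndarray,
                   p: ScoringParams) -> np.ndarray:
    """Vectorized ungapped expectation for every window start; miRNA
    position i pairs window position L-1-i."""
    L = len(mcodes)
    n_pos = len(tcodes) - L + 1
    if n_pos <= 0:
        return np.empty(0)
    scores = np.zeros(n_pos)
    pen = np.array([0.0, p.wobble, p.mismatch])
    w = _weights(L, p)
    for i in range(L):
        cls = _PAIR_CLASS[mcodes[i], tcodes[L - 1 - i:L - 1 - i + n_pos]]
        scores += w[i] * pen[cls]
    return scores


def _pen_matrix(mcodes, tcodes, p, shift, n_pos):
    """Rows i: weighted penalty of miRNA base i against the transcript
    base it pairs at window start `pos`, i.e. t[pos + shift - i]."""
    L = len(mcodes)
    pen = np.array([0.0, p.wobble, p.mismatch])
    w = _weights(L, p)
    out = np.empty((L, n_pos))
    for i in range(L):
        start = shift - i
        if start < 0 or start + n_pos > len(tcodes):
            out[i] = 0.0   # row never used by the caller's prefix sums
            continue
        sl = tcodes[start:start + n_pos]
        out[i] = w[i] * pen[_PAIR_CLASS[mcodes[i], sl]]
    return out


def _scan_gap_mirna(mcodes, tcodes, p) -> np.ndarray:
    """Min expectation over all single-miRNA-gap (target bulge)
    alignments, per window start; windows are miRNA length + 1."""
    L = len(mcodes)
    n_pos = len(tcodes) - (L + 1) + 1
    if n_pos <= 0:
        return np.empty(0)
    A = _pen_matrix(mcodes, tcodes, p, L - 1, n_pos)  # pairs t[pos+L-1-i]
    B = _pen_matrix(mcodes, tcodes, p, L, n_pos)      # pairs t[pos+L-i]
    prefB = np.vstack([np.zeros(n_pos), np.cumsum(B, axis=0)])
    sufA = np.vstack([np.cumsum(A[::-1], axis=0)[::-1],
                      np.zeros(n_pos)])
    best = np.full(n_pos, np.inf)
    for g in range(L + 1):
        gp = p.gap * _pos_weight(min(g, L - 1), p)
        np.minimum(best, prefB[g] + sufA[g] + gp, out=best)
    return best


def _scan_gap_target(mcodes, tcodes, p) -> np.ndarray:
    """Min expectation over all single-target-gap alignments, per window
    start; windows are miRNA length - 1."""
    L = len(mcodes)
    n_pos = len(tcodes) - (L - 1) + 1
    if n_pos <= 0 or L - 1 < 1:
        return np.empty(0)
    A = _pen_matrix(mcodes, tcodes, p, L - 1, n_pos)  # i > g: t[pos+L-1-i]
    D = _pen_matrix(mcodes, tcodes, p, L - 2, n_pos)  # i < g: t[pos+L-2-i]
    prefD = np.vstack([np.zeros(n_pos), np.cumsum(D, axis=0)])
    sufA = np.vstack([np.cumsum(A[::-1], axis=0)[::-1],
                      np.zeros(n_pos)])
    best = np.full(n_pos, np.inf)
    for g in range(L):
        gp = p.gap * _pos_weight(g, p)
        np.minimum(best, prefD[g] + sufA[g + 1] + gp, out=best)
    return best


def scan_targets(mirna_name: str, mirna: str,
                 transcriptome: dict[str, str],
                 params: ScoringParams | None = None,
                 compute_mfe: bool = True) -> list[TargetSite]:
    """All windows with expectation <= cutoff across the transcriptome,
    overlapping windows per unigene reduced to the best-scoring one."""
    p = params or ScoringParams()
    if p.cutoff <= 0:
        raise ValueError("cutoff must be positive")
    L = len(mirna)
    mcodes = np.array([_ENC[c] for c in mirna], dtype=np.int64)
    sites: list[TargetSite] = []
    for uid in sorted(transcriptome):
        seq = transcriptome[uid]
        tcodes = np.array([_ENC[c] for c in seq], dtype=np.int64)
        found: list[tuple[float, int, int]] = []
        scores = _scan_ungapped(mcodes, tcodes, p)
        for pos in np.flatnonzero(scores <= p.cutoff):
            found.append((float(scores[int(pos)]), int(pos), L))
        if p.max_gaps >= 1:
            for wlen, scores_g in (
                    (L + 1, _scan_gap_mirna(mcodes, tcodes, p)),
                    (L - 1, _scan_gap_target(mcodes, tcodes, p))):
                for pos in np.flatnonzero(scores_g <= p.cutoff):
                    found.append((float(scores_g[int(pos)]), int(pos),
                                  wlen))
        # best-scoring window per overlapping locus
        found.sort(key=lambda x: (x[0], x[1], x[2]))
        taken: list[tuple[int, int]] = []
        for score, pos, wlen in found:
            end = pos + wlen
            if any(pos < e and s < end for s, e in taken):
                continue
            taken.append((pos, end))
            window = seq[pos:end]
            exp, alignment = score_site(mirna, window, p)
            mfe = duplex_mfe(mirna, window) if compute_mfe else 0.0
            sites.append(TargetSite(mirna=mirna_name, unigene=uid,
                                    span=(pos, end), alignment=alignment,
                                    expectation=exp, duplex_mfe=mfe))
    sites.sort(key=lambda s: (s.expectation, s.unigene, s.span))
    return sites
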