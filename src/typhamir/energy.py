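"""Nearest-neighbor free-energy model for nested RNA secondary structure.

All energies are handled as integers in units of 0.01 kcal/mol (centi-kcal)
so that the dynamic-programming folder, the loop-decomposition evaluator and
any brute-force enumeration agree *exactly*, with no floating-point drift.

The parameter set is Turner-style: published Watson-Crick pair-stack free
energies at 37 degC, size-dependent hairpin/bulge/internal loop penalties
with a logarithmic extrapolation, a linear multiloop penalty, and G:U
wobble pairs allowed (with a simplified two-level wobble stacking term).
Sequences are DNA-alphabet internally (T == U).
"""

from __future__ import annotations

import math

import numpy as np

INF = 10**8          # sentinel: forbidden / uncomputed
SCALE = 100          # centi-kcal/mol per kcal/mol
MIN_HAIRPIN = 3      # minimum unpaired bases closed by a pair
MAX_LOOP = 30        # max total unpaired bases in a bulge/internal loop

# multiloop: a + b * (branches + 1), closing pair counted as a branch
ML_A = 340
ML_B = 40

BASES = "ACGT"
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair codes: 0 = not pairable, 1..6 = CG GC GU UG AU UA
PAIR_CODE = np.zeros((4, 4), dtype=np.int64)
PAIR_CODE[1, 2] = 1  # C-G
PAIR_CODE[2, 1] = 2  # G-C
PAIR_CODE[2, 3] = 3  # G-U
PAIR_CODE[3, 2] = 4  # U-G
PAIR_CODE[0, 3] = 5  # A-U
PAIR_CODE[3, 0] = 6  # U-A

_CG, _GC, _GU, _UG, _AU, _UA = 1, 2, 3, 4, 5, 6

# STACK[outer, inner]: pair (i,j) stacked over pair (i+1,j-1), centi-kcal.
# WC-WC entries are the Turner 2004 dG37 doublets; entries with one wobble
# pair are -120, with two wobble pairs -50 (see module docstring).
STACK = np.full((7, 7), INF, dtype=np.int64)
_WC_STACK = {
    (_AU, _AU): -93,
    (_AU, _UA): -110,
    (_UA, _AU): -133,
    (_UA, _UA): -93,
    (_CG, _UA): -208,
    (_CG, _AU): -211,
    (_GC, _UA): -224,
    (_GC, _AU): -235,
    (_CG, _GC): -236,
    (_CG, _CG): -326,
    (_GC, _GC): -326,
    (_GC, _CG): -342,
    (_AU, _GC): -208,
    (_AU, _CG): -224,
    (_UA, _GC): -211,
    (_UA, _CG): -235,
}
for (p, q), e in _WC_STACK.items():
    STACK[p, q] = e
for p in range(1, 7):
    for q in range(1, 7):
        n_gu = (p in (_GU, _UG)) + (q in (_GU, _UG))
        if n_gu == 1:
            STACK[p, q] = -120
        elif n_gu == 2:
            STACK[p, q] = -50

# size-dependent loop initiation penalties (centi-kcal); extrapolated
# beyond the table with 1.08 * ln(n / n_table) (1.75 RT at 37 degC)
_HAIRPIN = {3: 540, 4: 560, 5: 570, 6: 540, 7: 600, 8: 550, 9: 640}
_BULGE = {1: 380, 2: 280, 3: 320, 4: 360, 5: 400,
          6: 440, 7: 460, 8: 470, 9: 480, 10: 490}
_INTERNAL = {2: 150, 3: 180, 4: 200, 5: 220, 6: 250,
             7: 260, 8: 270, 9: 280, 10: 290}

_LOG_COEF = 108  # 1.75 * R * 310.15 in centi-kcal


def _extrapolate(table: dict, n: int, n_max: int) -> int:
    if n <= n_max:
        return table[n]
    return table[n_max] + int(round(_LOG_COEF * math.log(n / n_max)))


# precomputed dense tables so the jitted folder can index arrays
_TAB_N = 512  # longest loop we will ever see (sequences are <= ~500 nt)
HAIRPIN_TAB = np.full(_TAB_N, INF, dtype=np.int64)
for _n in range(MIN_HAIRPIN, _TAB_N):
    HAIRPIN_TAB[_n] = _extrapolate(_HAIRPIN, _n, 9)
BULGE_TAB = np.full(_TAB_N, INF, dtype=np.int64)
for _n in range(1, _TAB_N):
    BULGE_TAB[_n] = _extrapolate(_BULGE, _n, 10)
INTERNAL_TAB = np.full(_TAB_N, INF, dtype=np.int64)
for _n in range(2, _TAB_N):
    INTERNAL_TAB[_n] = _extrapolate(_INTERNAL, _n, 10)

ASYM_PENALTY = 50    # per unit of internal-loop asymmetry
ASYM_MAX = 300


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT/U sequence into int codes; raises on anything else."""
    try:
        return np.array([_ENC[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGTU symbol in sequence: {exc}") from None


def pair_code(a: int, b: int) -> int:
    return int(PAIR_CODE[a, b])


def hairpin_energy(n_unpaired: int) -> int:
    if n_unpaired < MIN_HAIRPIN:
        return INF
    return int(HAIRPIN_TAB[n_unpaired])


def loop_energy(n1: int, n2: int) -> int:
    """Penalty for a bulge/internal loop with n1 and n2 unpaired bases on
    the two sides (n1 + n2 > 0). Stacks (n1 == n2 == 0) are not handled
    here -- they take the sequence-dependent STACK term instead."""
    n = n1 + n2
    if n > MAX_LOOP:
        return INF
    if n1 == 0 or n2 == 0:
        return int(BULGE_TAB[n])
    asym = min(abs(n1 - n2) * ASYM_PENALTY, ASYM_MAX)
    return int(INTERNAL_TAB[n]) + asym


def multiloop_energy(n_branches: int) -> int:
    """Closing a multiloop with n_branches enclosed helices."""
    return ML_A + ML_B * (n_branches + 1)


def _children(pairs: list[tuple[int, int]], lo: int, hi: int):
    """Directly nested pairs inside (lo, hi), assuming sorted non-crossing
    input; returns top-level pairs with lo < i < j < hi."""
    out = []
    end = lo
    for (i, j) in pairs:
        if i <= lo or j >= hi:
            continue
        if i > end:
            out.append((i, j))
            end = j
    return out


def structure_energy(codes: np.ndarray, pairs: list[tuple[int, int]]) -> int:
    """Free energy (centi-kcal) of a given nested structure by loop
    decomposition. Independent of the DP folder; used as its oracle hook.

    Raises ValueError for crossing pairs, non-pairable bases or hairpin
    loops shorter than MIN_HAIRPIN.
    """
    n = len(codes)
    pairs = sorted(pairs)
    seen = set()
    for (i, j) in pairs:
        if not (0 <= i < j < n):
            raise ValueError("pair out of range")
        if i in seen or j in seen:
            raise ValueError("base in two pairs")
        seen.update((i, j))
        if PAIR_CODE[codes[i], codes[j]] == 0:
            raise ValueError("non-pairable bases")
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise ValueError("crossing pairs")

    total = 0
    stack = [(-1, n, False)]  # (i, j, closed_by_pair)
    while stack:
        lo, hi, closed = stack.pop()
        kids = _children(pairs, lo, hi)
        if closed:
            pc_out = PAIR_CODE[codes[lo], codes[hi]]
            if len(kids) == 0:
                total += hairpin_energy(hi - lo - 1)
            elif len(kids) == 1:
                (k, l) = kids[0]
                n1, n2 = k - lo - 1, hi - l - 1
                if n1 == 0 and n2 == 0:
                    total += int(STACK[pc_out, PAIR_CODE[codes[k], codes[l]]])
                else:
                    total += loop_energy(n1, n2)
            else:
                total += multiloop_energy(len(kids))
        for (k, l) in kids:
            stack.append((k, l, True))
    if total >= INF:
        raise ValueError("structure contains a forbidden loop")
    return total


def gc_percent(seq: str) -> float:
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for c in s if c in "GC") / len(s)
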