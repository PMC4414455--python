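"""Minimum-free-energy folding of single RNA strands and bimolecular
duplexes under the nearest-neighbor model in :mod:`typhamir.energy`.

`fold_rna` runs a Zuker-style dynamic program (hairpins, stacks, bulge and
internal loops bounded at MAX_LOOP unpaired bases, and linearly penalized
multiloops). All arithmetic is integer centi-kcal, the recursion fills are
deterministic, and traceback always takes the first minimal option in a
fixed enumeration order, so identical sequences give byte-identical
structures. `duplex_mfe` is the intermolecular analogue (no hairpins, no
intramolecular pairs), as used for miRNA:target hybrids.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .energy import (
    ASYM_MAX,
    ASYM_PENALTY,
    BULGE_TAB,
    HAIRPIN_TAB,
    INF,
    INTERNAL_TAB,
    MAX_LOOP,
    MIN_HAIRPIN,
    ML_A,
    ML_B,
    PAIR_CODE,
    SCALE,
    STACK,
    encode,
)

try:  # pragma: no cover - jit is an optimization, semantics identical
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket structure and MFE in kcal/mol."""

    dotbracket: str
    mfe: float

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def pair_table(self) -> list[int]:
        """partner index per position, -1 for unpaired."""
        pt = [-1] * len(self.dotbracket)
        stack = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pt[i], pt[j] = j, i
        return pt


@njit(cache=False)
def _loop_pen(n1, n2, bulge_tab, internal_tab):
    n = n1 + n2
    if n > MAX_LOOP:
        return INF
    if n1 == 0 or n2 == 0:
        return bulge_tab[n]
    asym = abs(n1 - n2) * ASYM_PENALTY
    if asym > ASYM_MAX:
        asym = ASYM_MAX
    return internal_tab[n] + asym


@njit(cache=False)
def _fill(codes, pair_tab, stack_tab, hairpin_tab, bulge_tab, internal_tab):
    n = codes.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            pc = pair_tab[codes[i], codes[j]]
            if pc > 0:
                best = hairpin_tab[j - i - 1]
                # stacks / bulges / internal loops
                for k in range(i + 1, j - MIN_HAIRPIN):
                    n1 = k - i - 1
                    if n1 > MAX_LOOP:
                        break
                    for l in range(j - 1, k + MIN_HAIRPIN, -1):
                        n2 = j - l - 1
                        if n1 + n2 > MAX_LOOP:
                            break
                        if V[k, l] >= INF:
                            continue
                        if n1 == 0 and n2 == 0:
                            pc_in = pair_tab[codes[k], codes[l]]
                            e = V[k, l] + stack_tab[pc, pc_in]
                        else:
                            e = V[k, l] + _loop_pen(n1, n2, bulge_tab,
                                                    internal_tab)
                        if e < best:
                            best = e
                # multiloop closed by (i, j)
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = ML_A + ML_B + WM[i + 1, k] + WM[k + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: >= 1 branch inside a multiloop, unpaired bases free
            wm = INF
            if V[i, j] < INF:
                wm = V[i, j] + ML_B
            if WM[i + 1, j] < wm:
                wm = WM[i + 1, j]
            if WM[i, j - 1] < wm:
                wm = WM[i, j - 1]
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    if e < wm:
                        wm = e
            WM[i, j] = wm
    # external loop
    W = np.zeros(n + 1, dtype=np.int64)
    for j in range(n):
        best = W[j]
        for i in range(j):
            if V[i, j] < INF:
                e = W[i] + V[i, j]
                if e < best:
                    best = e
        if V.shape[0] > 0 and j >= MIN_HAIRPIN + 1 and V[0, j] < INF:
            if V[0, j] < best:
                best = V[0, j]
        W[j + 1] = best
    return V, WM, W


def _traceback(codes, V, WM, W) -> list[tuple[int, int]]:
    n = len(codes)
    pairs: list[tuple[int, int]] = []
    jobs: list[tuple[str, int, int]] = []
    # external
    j = n - 1
    while j >= 0:
        if W[j + 1] == W[j]:
            j -= 1
            continue
        found = False
        for i in range(j + 1):
            base = W[i] if i > 0 else 0
            if V[i, j] < INF and base + V[i, j] == W[j + 1]:
                jobs.append(("V", i, j))
                j = i - 1
                found = True
                break
        assert found, "external traceback failed"

    while jobs:
        kind, i, j = jobs.pop()
        if kind == "V":
            pairs.append((i, j))
            e = V[i, j]
            if e == HAIRPIN_TAB[j - i - 1]:
                continue
            done = False
            for k in range(i + 1, j - MIN_HAIRPIN):
                n1 = k - i - 1
                if n1 > MAX_LOOP or done:
                    break
                for l in range(j - 1, k + MIN_HAIRPIN, -1):
                    n2 = j - l - 1
                    if n1 + n2 > MAX_LOOP:
                        break
                    if V[k, l] >= INF:
                        continue
                    if n1 == 0 and n2 == 0:
                        pc = PAIR_CODE[codes[i], codes[j]]
                        pc_in = PAIR_CODE[codes[k], codes[l]]
                        cand = V[k, l] + STACK[pc, pc_in]
                    else:
                        cand = V[k, l] + _loop_pen(n1, n2, BULGE_TAB,
                                                   INTERNAL_TAB)
                    if cand == e:
                        jobs.append(("V", k, l))
                        done = True
                        break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF and \
                        ML_A + ML_B + WM[i + 1, k] + WM[k + 1, j - 1] == e:
                    jobs.append(("M", i + 1, k))
                    jobs.append(("M", k + 1, j - 1))
                    done = True
                    break
            assert done, "V traceback failed"
        else:  # WM segment
            e = WM[i, j]
            if V[i, j] < INF and e == V[i, j] + ML_B:
                jobs.append(("V", i, j))
            elif i + 1 <= j and e == WM[i + 1, j]:
                jobs.append(("M", i + 1, j))
            elif j - 1 >= i and e == WM[i, j - 1]:
                jobs.append(("M", i, j - 1))
            else:
                done = False
                for k in range(i + 1, j):
                    if WM[i, k] < INF and WM[k + 1, j] < INF and \
                            WM[i, k] + WM[k + 1, j] == e:
                        jobs.append(("M", i, k))
                        jobs.append(("M", k + 1, j))
                        done = True
                        break
                assert done, "WM traceback failed"
    return pairs


@lru_cache(maxsize=4096)
def fold_rna(sequence: str) -> FoldResult:
    """Fold a single strand to its minimum-free-energy nested structure.

    Accepts ACGT/U; raises ValueError on other symbols or on sequences
    longer than 500 nt. Returns the open chain (all dots, MFE 0) when no
    structure has negative energy.
    """
    if not 1 <= len(sequence) <= 500:
        raise ValueError("sequence length must be in [1, 500]")
    codes = encode(sequence)
    n = len(codes)
    if n < MIN_HAIRPIN + 2:
        return FoldResult("." * n, 0.0)
    V, WM, W = _fill(codes, PAIR_CODE, STACK, HAIRPIN_TAB, BULGE_TAB,
                     INTERNAL_TAB)
    mfe_int = int(W[n])
    if mfe_int >= 0:
        return FoldResult("." * n, 0.0)
    pairs = _traceback(codes, V, WM, W)
    db = ["."] * n
    for (i, j) in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult("".join(db), mfe_int / SCALE)


def mfei(mfe: float, length: int, gc_pct: float) -> float:
    """Minimal folding free energy index: (MFE / length * 100) / GC%."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_pct <= 100:
        raise ValueError("gc_percent must be in (0, 100]")
    return (mfe / length * 100.0) / gc_pct


MAX_LOOP_DUPLEX = 15


def _duplex_fill(c1: np.ndarray, c2: np.ndarray):
    """D[i, j] = best energy of a duplex whose innermost (most recent)
    pair is s1[i] : s2[j]; pairs advance 5'->3' on s1 and 3'->5' on s2."""
    n1, n2 = len(c1), len(c2)
    D = np.full((n1, n2), INF, dtype=np.int64)
    for i in range(n1):
        for j in range(n2 - 1, -1, -1):
            pc = PAIR_CODE[c1[i], c2[j]]
            if pc == 0:
                continue
            best = 0  # helix start, no initiation penalty
            for ip in range(max(0, i - MAX_LOOP_DUPLEX - 1), i):
                g1 = i - ip - 1
                for jp in range(j + 1, min(n2, j + MAX_LOOP_DUPLEX + 2 - g1)):
                    if D[ip, jp] >= INF:
                        continue
                    g2 = jp - j - 1
                    if g1 == 0 and g2 == 0:
                        pc_out = PAIR_CODE[c1[ip], c2[jp]]
                        e = D[ip, jp] + int(STACK[pc_out, pc])
                    else:
                        e = D[ip, jp] + _loop_pen(g1, g2, BULGE_TAB,
                                                  INTERNAL_TAB)
                    if e < best:
                        best = e
            D[i, j] = best
    return D


def duplex_mfe(seq1: str, seq2: str) -> float:
    """Minimum free energy (kcal/mol, <= 0) of the intermolecular duplex
    of two strands, both given 5'->3'; intramolecular pairs excluded."""
    c1, c2 = encode(seq1), encode(seq2)
    if len(c1) == 0 or len(c2) == 0:
        return 0.0
    D = _duplex_fill(c1, c2)
    best = int(D.min()) if D.size else INF
    return min(best, 0) / SCALE


def duplex_structure_energy(c1: np.ndarray, c2: np.ndarray,
                            pairs: list[tuple[int, int]]) -> int:
    """Energy (centi-kcal) of an explicit duplex pairing: pairs sorted by
    s1 index must have strictly decreasing s2 indices (antiparallel,
    non-crossing). Used by brute-force oracles."""
    if not pairs:
        return 0
    pairs = sorted(pairs)
    total = 0
    for idx, (i, j) in enumerate(pairs):
        pc = PAIR_CODE[c1[i], c2[j]]
        if pc == 0:
            raise ValueError("non-pairable bases")
        if idx:
            ip, jp = pairs[idx - 1]
            if jp <= j:
                raise ValueError("crossing duplex pairs")
            g1, g2 = i - ip - 1, jp - j - 1
            if g1 == 0 and g2 == 0:
                pc_out = PAIR_CODE[c1[ip], c2[jp]]
                total += int(STACK[pc_out, pc])
            else:
                total += _loop_pen(g1, g2, BULGE_TAB, INTERNAL_TAB)
    if total >= INF:
        raise ValueError("forbidden loop in duplex")
    return total
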