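"""Brute-force oracles used by unit and acceptance tests.

These enumerate structures or sum series directly from first principles;
they share only the energy *parameter tables* with the implementation,
never its dynamic programs.
"""

import numpy as np
from scipy.special import gammaln

from typhamir.energy import MIN_HAIRPIN, PAIR_CODE, encode, structure_energy
from typhamir.fold import duplex_structure_energy


def enumerate_structures(codes):
    """Yield every nested set of allowed pairs (min hairpin loop 3)."""
    n = len(codes)
    allowed = [[PAIR_CODE[codes[i], codes[j]] > 0 and j - i > MIN_HAIRPIN
                for j in range(n)] for i in range(n)]

    def rec(positions):
        if not positions:
            yield []
            return
        first, rest = positions[0], positions[1:]
        yield from rec(rest)
        for j in rest:
            if allowed[first][j]:
                inside = [p for p in rest if first < p < j]
                outside = [p for p in rest if p > j]
                for s1 in rec(inside):
                    for s2 in rec(outside):
                        yield [(first, j)] + s1 + s2

    yield from rec(list(range(n)))


def brute_force_mfe(seq: str) -> float:
    """Exhaustive-enumeration MFE (kcal/mol) for short sequences."""
    codes = encode(seq)
    best = 0
    for pairs in enumerate_structures(codes):
        if not pairs:
            continue
        try:
            e = structure_energy(codes, pairs)
        except ValueError:
            continue
        best = min(best, e)
    return best / 100.0


def brute_force_duplex_mfe(seq1: str, seq2: str) -> float:
    """Exhaustive enumeration of antiparallel non-crossing duplex
    pairings between two short strands."""
    c1, c2 = encode(seq1), encode(seq2)
    pairable = [(i, j) for i in range(len(c1)) for j in range(len(c2))
                if PAIR_CODE[c1[i], c2[j]] > 0]
    best = 0

    def rec(start_i, max_j, chosen):
        nonlocal best
        if chosen:
            try:
                best = min(best, duplex_structure_energy(c1, c2, chosen))
            except ValueError:
                pass
        for (i, j) in pairable:
            if i >= start_i and j < max_j:
                rec(i + 1, j, chosen + [(i, j)])

    rec(0, len(c2), [])
    return best / 100.0


def audic_claverie_direct(x: int, N1: float, y: int, N2: float,
                          tail_span: int = 12) -> float:
    """Two-sided Audic-Claverie p by direct log-space summation of
    p(k|x) = r^k (x+k)! / (x! k! (1+r)^(x+k+1)), r = N2/N1."""
    r = N2 / N1
    log_r = np.log(r)
    log_1r = np.log1p(r)

    def log_pmf(k):
        return (k * log_r + gammaln(x + k + 1) - gammaln(x + 1)
                - gammaln(k + 1) - (x + k + 1) * log_1r)

    # sum far enough into each tail for the mass to be negligible
    upper_stop = int((x + y + 10) * max(r, 1.0) * 4 + tail_span * 50)
    lower = np.exp([log_pmf(k) for k in range(0, y + 1)]).sum()
    upper = np.exp([log_pmf(k) for k in range(y, upper_stop)]).sum()
    return float(min(1.0, 2.0 * min(lower, upper)))
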