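"""Conserved miRNA matching, novel miRNA prediction from transcript
hairpins, 5p/3p duplex detection and isomiR enumeration.

Conserved miRNAs: tags are matched to a known-mature reference allowing a
length difference of up to 2 nt and a Hamming distance of up to 2 over the
aligned core (no indels), then clustered per reference; the dominant-count
member represents the cluster and expression is the summed counts of
members passing the class rule.

Novel miRNAs: tags perfectly mapped to transcripts seed hairpin windows
that are folded; a candidate precursor is accepted when the mature lies
wholly in one arm with at most 4 unpaired bases (at most 2 consecutive),
at least 16 bases paired, MFE <= -18 kcal/mol, MFEI <= -0.5 and precursor
length within [68, 300]. These thresholds follow the common plant-miRNA
(Mireap-style) convention and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import map_perfect
from .energy import gc_percent
from .fold import FoldResult, fold_rna, mfei
from .io import revcomp


@dataclass
class NovelParams:
    flank: int = 150
    min_count: int = 3
    mature_min: int = 18
    mature_max: int = 26
    max_unpaired: int = 4
    max_consecutive_unpaired: int = 2
    min_paired: int = 16
    max_mfe: float = -18.0
    max_mfei: float = -0.5
    min_precursor: int = 68
    max_precursor: int = 300


@dataclass
class PreMiRNACandidate:
    source_unigene: str
    span: tuple[int, int]          # 0-based half-open on the transcript
    strand: str                    # '+' or '-' relative to the transcript
    sequence: str
    fold: FoldResult
    mfe: float
    mfei: float
    mature_span: tuple[int, int]   # on the precursor
    arm: str                       # '5p' | '3p'
    arm_5p: tuple[int, int] | None = None
    arm_3p: tuple[int, int] | None = None


@dataclass
class MatureMiRNARecord:
    name: str
    mirna_class: str               # 'conserved' | 'novel'
    representative_seq: str
    cluster_members: list = field(default_factory=list)
    precursor: PreMiRNACandidate | None = None
    expr_ck: int = 0
    expr_cd: int = 0
    star_seq: str | None = None    # partner-arm sequence when paired


@dataclass
class IsomiR:
    parent: str
    sequence: str
    offset_5p: int                 # positive = trimmed at the 5' end
    offset_3p: int                 # positive = trimmed at the 3' end
    count_ck: int
    count_cd: int
    is_canonical: bool


# ---------------------------------------------------------------------------
# conserved matching


def _hamming_core(short: str, long: str):
    """Best (mismatches, offset) sliding the shorter sequence along the
    longer; mismatches counted over the aligned core only."""
    best = (len(short) + 1, 0)
    for off in range(len(long) - len(short) + 1):
        mm = sum(a != b for a, b in zip(short, long[off:off + len(short)]))
        if mm < best[0]:
            best = (mm, off)
    return best


def match_conserved(tags, mature_reference: dict[str, str],
                    max_mismatch: int = 2, max_len_diff: int = 2):
    """Best reference hit per tag (min mismatches, ties by reference
    name); a hit requires |length difference| <= 2 and Hamming distance
    <= 2 at the best offset. Returns {tag_sequence: (ref_name, mm)}."""
    ref_items = sorted(mature_reference.items())
    by_len: dict[int, list[tuple[str, str]]] = {}
    for name, seq in ref_items:
        by_len.setdefault(len(seq), []).append((name, seq))
    out: dict[str, tuple[str, int]] = {}
    for tag in tags:
        seq = tag if isinstance(tag, str) else tag.sequence
        best: tuple[int, str] | None = None
        for ln in range(len(seq) - max_len_diff,
                        len(seq) + max_len_diff + 1):
            for name, ref in by_len.get(ln, ()):
                short, long_ = (seq, ref) if len(seq) <= ln else (ref, seq)
                mm, _ = _hamming_core(short, long_)
                if mm <= max_mismatch and \
                        (best is None or (mm, name) < best):
                    best = (mm, name)
        if best is not None:
            out[seq] = (best[1], best[0])
    return out


def _novel_rule_ok(member: str, representative: str,
                   terminal: int = 3, max_mm: int = 3) -> bool:
    """Expression-summation rule for novel clusters: differences confined
    to the outermost `terminal` nt of each end (trims/extensions counted
    per nt), middle exact, and at most `max_mm` in total."""
    mm, off = _hamming_core(*((member, representative)
                              if len(member) <= len(representative)
                              else (representative, member)))
    short, long_ = (member, representative) \
        if len(member) <= len(representative) else (representative, member)
    # recompute at the best offset to localize substitutions
    best = None
    for o in range(len(long_) - len(short) + 1):
        subs = [i for i, (a, b) in
                enumerate(zip(short, long_[o:o + len(short)])) if a != b]
        end5 = o
        end3 = len(long_) - len(short) - o
        total = end5 + end3 + len(subs)
        mid_ok = all(i < terminal or i >= len(short) - terminal
                     for i in subs)
        ok = mid_ok and end5 <= terminal and end3 <= terminal \
            and total <= max_mm
        if best is None or (not best[0] and ok) or \
                (ok and best[0] and total < best[1]):
            best = (ok, total)
    return bool(best and best[0])


def _conserved_rule_ok(member: str, representative: str,
                       max_mm: int = 2) -> bool:
    short, long_ = (member, representative) \
        if len(member) <= len(representative) else (representative, member)
    if len(long_) - len(short) > 2:
        return False
    mm, _ = _hamming_core(short, long_)
    return mm <= max_mm


def cluster_and_quantify(groups: dict[str, list], tags_by_seq: dict,
                         terminal_rule: str) -> list[MatureMiRNARecord]:
    """Per group (reference name or precursor id -> member sequences):
    representative = dominant-count member (ties: lexicographically
    smallest); expression = summed counts of members passing the class
    rule ('conserved': <=2 mismatches anywhere; 'novel': mismatches only
    in the outer 3 nt of each end, middle exact, <=3 total)."""
    if terminal_rule not in ("conserved", "novel"):
        raise ValueError("terminal_rule must be 'conserved' or 'novel'")
    records = []
    for gname in sorted(groups):
        members = sorted(set(groups[gname]))
        if not members:
            continue
        rep = min(members, key=lambda s: (-tags_by_seq[s].total, s))
        rule = _conserved_rule_ok if terminal_rule == "conserved" \
            else _novel_rule_ok
        kept = [m for m in members if rule(m, rep)]
        expr_ck = sum(tags_by_seq[m].count_ck for m in kept)
        expr_cd = sum(tags_by_seq[m].count_cd for m in kept)
        records.append(MatureMiRNARecord(
            name=gname, mirna_class=terminal_rule, representative_seq=rep,
            cluster_members=kept, expr_ck=expr_ck, expr_cd=expr_cd))
    return records


# ---------------------------------------------------------------------------
# novel prediction


def _mature_pairing(fold: FoldResult, m0: int, m1: int):
    """(n_paired, max_consecutive_unpaired, partners) for mature span
    [m0, m1) on a folded precursor."""
    pt = fold.pair_table()
    partners = [pt[i] for i in range(m0, m1)]
    paired = [p for p in partners if p >= 0]
    run = best_run = 0
    for p in partners:
        run = run + 1 if p < 0 else 0
        best_run = max(best_run, run)
    return len(paired), best_run, paired


def _check_candidate(seq: str, m0: int, m1: int,
                     params: NovelParams):
    """Fold `seq` and test all precursor criteria for the mature at
    [m0, m1); returns (FoldResult, arm) or None."""
    if not params.min_precursor <= len(seq) <= params.max_precursor:
        return None
    fold = fold_rna(seq)
    if fold.mfe >= 0:
        return None
    n_paired, max_run, partners = _mature_pairing(fold, m0, m1)
    m_len = m1 - m0
    if m_len - n_paired > params.max_unpaired:
        return None
    if max_run > params.max_consecutive_unpaired:
        return None
    if n_paired < params.min_paired:
        return None
    if all(p >= m1 for p in partners):
        arm = "5p"
    elif all(p < m0 for p in partners):
        arm = "3p"
    else:
        return None  # mature straddles the loop
    if fold.mfe > params.max_mfe:
        return None
    if mfei(fold.mfe, len(seq), gc_percent(seq)) > params.max_mfei:
        return None
    return fold, arm


def _enclosing_pair(fold: FoldResult, m0: int, m1: int):
    """Outermost base pair (a, b) with a <= m0 and b >= m1 - 1."""
    pt = fold.pair_table()
    for a in range(m0 + 1):
        b = pt[a]
        if b >= m1 - 1 and b > a:
            return a, b
    return None


def predict_novel(tags, transcriptome: dict[str, str],
                  params: NovelParams | None = None,
                  exclude: set[str] | None = None):
    """Hairpin-based novel miRNA prediction.

    Returns (candidates, records): accepted PreMiRNACandidate objects
    (merged per overlapping precursor locus) and one MatureMiRNARecord per
    candidate with novel-rule expression sums, named novel_mir_N in order
    of descending expression.
    """
    params = params or NovelParams()
    exclude = exclude or set()
    tags_by_seq = {t.sequence: t for t in tags}
    eligible = [t for t in tags
                if params.mature_min <= len(t.sequence) <= params.mature_max
                and t.total >= params.min_count
                and t.sequence not in exclude]
    eligible.sort(key=lambda t: (-t.total, t.sequence))
    hits = map_perfect(eligible, transcriptome)

    raw: list[tuple[PreMiRNACandidate, str]] = []
    for seq, uid, pos in hits:
        ref = transcriptome[uid]
        t_end = pos + len(seq)
        # a tag falling inside an already-accepted precursor locus is a
        # length/sequence variant of its mature, not a new seed
        if any(c.source_unigene == uid and c.span[0] <= pos
               and t_end <= c.span[1] for c, _ in raw):
            continue
        for cand in _candidates_for_hit(seq, uid, pos, ref, params):
            raw.append((cand, seq))

    merged = _merge_candidates(raw)
    # attach cluster members: tags that are substrings of the precursor
    # and overlap the mature span by >= 50% of the mature length
    records = []
    for cand, mature_seq in merged:
        members = _precursor_members(cand, tags, min_overlap=0.5)
        groups = {"cand": members or [mature_seq]}
        rec = cluster_and_quantify(groups, tags_by_seq, "novel")[0]
        rec.precursor = cand
        records.append(rec)
    records.sort(key=lambda r: (-(r.expr_ck + r.expr_cd),
                                r.precursor.source_unigene,
                                r.precursor.span))
    for i, rec in enumerate(records):
        rec.name = f"novel_mir_{i + 1}"
    return [r.precursor for r in records], records


def _candidates_for_hit(seq: str, uid: str, pos: int, ref: str,
                        params: NovelParams):
    """All accepted precursor candidates for one perfect hit of a mature
    tag at `pos` on transcript `ref`: two flanking windows, both
    orientations."""
    t_end = pos + len(seq)
    out = []
    seen: set[tuple] = set()
    for w0, w1 in ((max(0, pos - params.flank), min(len(ref), t_end + 20)),
                   (max(0, pos - 20), min(len(ref), t_end + params.flank))):
        for strand in "+-":
            if (w0, w1, strand) in seen:
                continue
            seen.add((w0, w1, strand))
            window = ref[w0:w1]
            if strand == "-":
                window = revcomp(window)
                m0 = w1 - t_end
            else:
                m0 = pos - w0
            m1 = m0 + len(seq)
            res = _check_window(window, m0, m1, params)
            if res is None:
                continue
            pre_seq, pre_m0, fold, arm, off = res
            pre_m1 = pre_m0 + len(seq)
            if strand == "+":
                span = (w0 + off, w0 + off + len(pre_seq))
            else:
                span = (w1 - off - len(pre_seq), w1 - off)
            cand = PreMiRNACandidate(
                source_unigene=uid, span=span, strand=strand,
                sequence=pre_seq, fold=fold, mfe=fold.mfe,
                mfei=mfei(fold.mfe, len(pre_seq), gc_percent(pre_seq)),
                mature_span=(pre_m0, pre_m1), arm=arm)
            if arm == "5p":
                cand.arm_5p = (pre_m0, pre_m1)
            else:
                cand.arm_3p = (pre_m0, pre_m1)
            out.append(cand)
    return out


def find_precursor(seq: str, transcriptome: dict[str, str],
                   params: NovelParams | None = None
                   ) -> PreMiRNACandidate | None:
    """Best (lowest-MFE) accepted precursor for one mature sequence over
    the whole transcriptome, or None."""
    params = params or NovelParams()
    best = None
    for uid in sorted(transcriptome):
        ref = transcriptome[uid]
        pos = ref.find(seq)
        while pos >= 0:
            for cand in _candidates_for_hit(seq, uid, pos, ref, params):
                if best is None or (cand.strand != "+", cand.mfe) < \
                        (best.strand != "+", best.mfe):
                    best = cand
            pos = ref.find(seq, pos + 1)
    return best


def _check_window(window: str, m0: int, m1: int, params: NovelParams):
    """Fold a search window, trim to the hairpin enclosing the mature,
    re-fold and re-check; returns (precursor_seq, mature_offset,
    FoldResult, arm, precursor_offset_in_window) or None."""
    if len(window) < params.min_precursor:
        return None
    fold = fold_rna(window)
    if fold.mfe >= 0:
        return None
    enc = _enclosing_pair(fold, m0, m1)
    if enc is None:
        return None
    a, b = enc
    pre_seq = window[a:b + 1]
    pre_m0 = m0 - a
    res = _check_candidate(pre_seq, pre_m0, pre_m0 + (m1 - m0), params)
    if res is None:
        return None
    pre_fold, arm = res
    return pre_seq, pre_m0, pre_fold, arm, a


def _merge_candidates(raw):
    """Merge candidates sharing a precursor locus (same unigene,
    overlapping spans, either orientation); sense-strand candidates are
    preferred, then lower MFE."""
    def rank(c: PreMiRNACandidate):
        return (c.strand != "+", c.mfe)

    merged: list[list] = []
    for cand, seq in sorted(raw, key=lambda cs: (cs[0].source_unigene,
                                                 cs[0].span)):
        placed = False
        for slot in merged:
            other = slot[0]
            if other.source_unigene == cand.source_unigene and \
                    cand.span[0] < other.span[1] and \
                    other.span[0] < cand.span[1]:
                if rank(cand) < rank(other):
                    slot[0], slot[1] = cand, seq
                placed = True
                break
        if not placed:
            merged.append([cand, seq])
    return [(c, s) for c, s in merged]


def _precursor_members(cand: PreMiRNACandidate, tags,
                       min_overlap: float) -> list[str]:
    m0, m1 = cand.mature_span
    need = (m1 - m0) * min_overlap
    out = []
    for t in tags:
        pos = cand.sequence.find(t.sequence)
        while pos >= 0:
            overlap = min(pos + len(t.sequence), m1) - max(pos, m0)
            if overlap >= need:
                out.append(t.sequence)
                break
            pos = cand.sequence.find(t.sequence, pos + 1)
    return sorted(set(out))


# ---------------------------------------------------------------------------
# 5p/3p pairs and isomiRs


def detect_star(candidate: PreMiRNACandidate, tags,
                overhang: int = 2, tolerance: int = 1,
                min_count: int = 1) -> str | None:
    """Partner-arm (star) sequence when an expressed tag maps to the
    opposite arm forming a duplex with ~2-nt 3' overhangs (+-1 nt).

    The expected star runs from the partner of mature position
    (end - 1 - overhang) to `overhang` nt past the partner of the mature
    5' end -- the standard Dicer duplex geometry -- on either arm."""
    pt = candidate.fold.pair_table()
    m0, m1 = candidate.mature_span

    def partner_near(i):
        # nearest paired mature base to position i, preferring i itself
        # pairing is antiparallel, so partner(i) ~ partner(k) + (k - i)
        for d in range(0, m1 - m0):
            for k in (i - d, i + d):
                if m0 <= k < m1 and pt[k] >= 0:
                    return pt[k] + (k - i)
        return None

    p_star5 = partner_near(m1 - 1 - overhang)  # pairs the star 5' end
    p_star3 = partner_near(m0)                 # pairs the star 3' end
    if p_star5 is None or p_star3 is None:
        return None
    exp_start = min(p_star5, p_star3)
    exp_end = max(p_star5, p_star3) + overhang + 1

    best = None
    for t in tags:
        if t.total < min_count:
            continue
        pos = candidate.sequence.find(t.sequence)
        if pos < 0:
            continue
        end = pos + len(t.sequence)
        # must sit on the opposite arm
        if candidate.arm == "5p" and pos < m1:
            continue
        if candidate.arm == "3p" and end > m0:
            continue
        if abs(pos - exp_start) <= tolerance and \
                abs(end - exp_end) <= tolerance + 1:
            if best is None or t.total > best[0]:
                best = (t.total, t.sequence)
    return best[1] if best else None


def enumerate_isomirs(record: MatureMiRNARecord, tags,
                      min_overlap: float = 0.5) -> list[IsomiR]:
    """All tags aligning to the record's precursor and overlapping the
    mature span by >= `min_overlap` of the mature length, with signed
    5'/3' offsets relative to the canonical mature (positive = trimmed,
    negative = extended)."""
    if record.precursor is None:
        raise ValueError("record has no precursor")
    cand = record.precursor
    m0, m1 = cand.mature_span
    need = (m1 - m0) * min_overlap
    out = []
    for t in sorted(tags, key=lambda t: (-t.total, t.sequence)):
        pos = cand.sequence.find(t.sequence)
        while pos >= 0:
            end = pos + len(t.sequence)
            overlap = min(end, m1) - max(pos, m0)
            if overlap >= need:
                out.append(IsomiR(
                    parent=record.name, sequence=t.sequence,
                    offset_5p=pos - m0, offset_3p=m1 - end,
                    count_ck=t.count_ck, count_cd=t.count_cd,
                    is_canonical=(pos == m0 and end == m1)))
                break
            pos = cand.sequence.find(t.sequence, pos + 1)
    return out


def dominant_isomir_differs(isomirs: list[IsomiR]) -> bool:
    """True when the most abundant isomiR is not the canonical mature."""
    if not isomirs:
        return False
    top = max(isomirs, key=lambda i: (i.count_ck + i.count_cd,
                                      i.is_canonical))
    return not top.is_canonical
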