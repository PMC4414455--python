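"""Read cleaning, tag collapsing, and the length / first-base summaries.

Cleaning applies, in order: a quality filter (>10% of bases below Phred 20,
or any N), a 5'-adapter contaminant filter, 3'-adapter trimming (reads with
no recognizable 3' adapter, or an empty insert from adapter-adapter
ligation, are discarded), a poly(A) filter, and a length filter keeping
15-30 nt inserts. The first failing rule is the one counted, so raw read
counts are conserved exactly across the removal reasons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .synthetic import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5

MIN_LEN, MAX_LEN = 15, 30

REASONS = ("low_quality", "contaminant_5p", "no_insert", "polya",
           "too_short", "too_long")


@dataclass
class CleanStats:
    raw_reads: int = 0
    removed_by_reason: dict = field(default_factory=dict)
    clean_reads: int = 0

    def validate(self) -> None:
        if self.raw_reads != self.clean_reads + \
                sum(self.removed_by_reason.values()):
            raise AssertionError("read-count conservation violated")

    def as_frame(self) -> pd.DataFrame:
        rows = [{"metric": "raw_reads", "count": self.raw_reads}]
        rows += [{"metric": f"removed_{r}",
                  "count": self.removed_by_reason.get(r, 0)}
                 for r in REASONS]
        rows.append({"metric": "clean_reads", "count": self.clean_reads})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SmallRNATag:
    """A unique cleaned insert sequence with per-library counts."""

    sequence: str
    count_ck: int
    count_cd: int

    @property
    def total(self) -> int:
        return self.count_ck + self.count_cd


def trim_adapter(read: str, adapter3: str = DEFAULT_ADAPTER3) -> str | None:
    """Insert upstream of the left-most match of the adapter's first 8 nt;
    falls back to the longest (>= 6 nt) adapter prefix that ends the read.
    None when no adapter is found or the insert is empty."""
    if len(adapter3) < 6:
        raise ValueError("adapter3 must be >= 6 nt")
    probe = adapter3[:8]
    pos = read.find(probe)
    if pos < 0:
        # partial adapter running off the 3' end of the read
        max_k = min(len(adapter3), len(read))
        for k in range(max_k, 5, -1):
            if read.endswith(adapter3[:k]):
                pos = len(read) - k
                break
        else:
            return None
    return read[:pos] or None


def _is_low_quality(seq: str, qual: str | None) -> bool:
    if "N" in seq:
        return True
    if qual is None:
        return False
    n_low = sum(1 for c in qual if ord(c) - 33 < 20)
    return n_low > 0.1 * len(qual)


def _is_polya(insert: str) -> bool:
    if not insert:
        return False
    if insert.count("A") >= 0.8 * len(insert):
        return True
    return insert.endswith("A" * 8)


def _is_contaminant_5p(read: str, adapter5: str) -> bool:
    tail = adapter5[-8:]
    head = read[:8]
    if len(head) < 8:
        return False
    return sum(a != b for a, b in zip(head, tail)) <= 1


def clean_library(reads, adapter3: str = DEFAULT_ADAPTER3,
                  adapter5: str = DEFAULT_ADAPTER5):
    """Clean raw reads -> (list of insert sequences, CleanStats).

    `reads` holds (sequence, quality) pairs or bare sequences (then the
    quality filter only checks for N).
    """
    stats = CleanStats(removed_by_reason={r: 0 for r in REASONS})
    inserts: list[str] = []
    for item in reads:
        seq, qual = item if isinstance(item, tuple) else (item, None)
        seq = seq.upper()
        stats.raw_reads += 1
        if _is_low_quality(seq, qual):
            stats.removed_by_reason["low_quality"] += 1
            continue
        if _is_contaminant_5p(seq, adapter5):
            stats.removed_by_reason["contaminant_5p"] += 1
            continue
        insert = trim_adapter(seq, adapter3)
        if insert is None:
            stats.removed_by_reason["no_insert"] += 1
            continue
        if _is_polya(insert):
            stats.removed_by_reason["polya"] += 1
            continue
        if len(insert) < MIN_LEN:
            stats.removed_by_reason["too_short"] += 1
            continue
        if len(insert) > MAX_LEN:
            stats.removed_by_reason["too_long"] += 1
            continue
        inserts.append(insert)
    stats.clean_reads = len(inserts)
    stats.validate()
    return inserts, stats


def collapse_tags(inserts_ck, inserts_cd) -> list[SmallRNATag]:
    """One tag per distinct sequence with per-library counts, ordered by
    descending total count then lexicographically."""
    ck = Counter(inserts_ck)
    cd = Counter(inserts_cd)
    tags = [SmallRNATag(seq, ck.get(seq, 0), cd.get(seq, 0))
            for seq in set(ck) | set(cd)]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def length_distribution(tags, by: str = "total") -> pd.DataFrame:
    """Per-length percentage per library over 14-30 nt (occupied lengths).

    `by='total'` weights each tag by its read count (redundant sequences);
    `by='unique'` counts each distinct tag once.
    """
    if by not in ("total", "unique"):
        raise ValueError("by must be 'total' or 'unique'")
    rows = {}
    for tag in tags:
        n = len(tag.sequence)
        w_ck = tag.count_ck if by == "total" else int(tag.count_ck > 0)
        w_cd = tag.count_cd if by == "total" else int(tag.count_cd > 0)
        r = rows.setdefault(n, [0, 0])
        r[0] += w_ck
        r[1] += w_cd
    df = pd.DataFrame([{"length": n, "ck": v[0], "cd": v[1]}
                       for n, v in sorted(rows.items())])
    if df.empty:
        return pd.DataFrame(columns=["length", "pct_ck", "pct_cd"])
    for col in ("ck", "cd"):
        total = df[col].sum()
        df[f"pct_{col}"] = 100.0 * df[col] / total if total else 0.0
    return df[["length", "ck", "cd", "pct_ck", "pct_cd"]]


def first_base_bias(tags) -> pd.DataFrame:
    """Fraction of unique tags beginning with each base, per length 18-25.
    Rows sum to 1; empty length classes are omitted. The T column is the
    5'-uridine fraction in RNA notation."""
    counts: dict[int, Counter] = {}
    for tag in tags:
        n = len(tag.sequence)
        if 18 <= n <= 25:
            counts.setdefault(n, Counter())[tag.sequence[0]] += 1
    rows = []
    for n in sorted(counts):
        total = sum(counts[n].values())
        row = {"length": n}
        for base in "ACGT":
            row[base] = counts[n].get(base, 0) / total
        rows.append(row)
    return pd.DataFrame(rows, columns=["length", "A", "C", "G", "T"])
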