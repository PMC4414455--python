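"""Single-category annotation of unique tags and the composition summary.

Each tag receives exactly one category following the priority rule
ncRNA (GenBank consulted before Rfam; within a source
rRNA > tRNA > snRNA > snoRNA) > known miRNA > other reference >
unannotated. Matching is exact substring on the sense strand, consistent
with retaining only perfectly matching reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

NCRNA_TYPES = ("rRNA", "tRNA", "snRNA", "snoRNA")
CATEGORIES = NCRNA_TYPES + ("known_miRNA", "other_reference", "unannotated")


@dataclass
class ReferenceSet:
    """A FASTA-backed reference collection: `types` maps record id to its
    declared RNA class (for ncRNA sets); `source` is GenBank or Rfam."""

    name: str
    source: str
    records: dict[str, str]
    types: dict[str, str] = field(default_factory=dict)


def map_perfect(tags, reference: dict[str, str]):
    """All (tag_sequence, record_id, offset) exact sense-strand substring
    hits, offsets 0-based; every occurrence is reported."""
    hits = []
    for tag in tags:
        seq = tag if isinstance(tag, str) else tag.sequence
        for rid, ref in reference.items():
            start = ref.find(seq)
            while start >= 0:
                hits.append((seq, rid, start))
                start = ref.find(seq, start + 1)
    return hits


def _hit_sequences(hits) -> set[str]:
    return {h[0] for h in hits}


@dataclass
class AnnotationResult:
    category: dict[str, str]          # tag sequence -> category
    source: dict[str, str]            # tag sequence -> GenBank|Rfam|none

    def validate(self, tags) -> None:
        for tag in tags:
            if tag.sequence not in self.category:
                raise AssertionError("tag without category")


def classify_tag(seq: str, ncrna_hits_by_source, mirna_hit: bool,
                 other_hit: bool) -> tuple[str, str]:
    """Category and source for one tag. `ncrna_hits_by_source` maps
    'GenBank' / 'Rfam' to the set of ncRNA types the tag hit there."""
    for source in ("GenBank", "Rfam"):
        types = ncrna_hits_by_source.get(source) or ()
        for t in NCRNA_TYPES:
            if t in types:
                return t, source
    if mirna_hit:
        return "known_miRNA", "none"
    if other_hit:
        return "other_reference", "none"
    return "unannotated", "none"


def annotate_tags(tags, ncrna_refs, mature_ref: dict[str, str],
                  other_ref: dict[str, str] | None = None
                  ) -> AnnotationResult:
    """Assign every tag exactly one category using the priority rule."""
    per_source: dict[str, dict[str, set]] = {}
    for refset in ncrna_refs:
        store = per_source.setdefault(refset.source, {})
        for seq, rid, _ in map_perfect(tags, refset.records):
            store.setdefault(seq, set()).add(refset.types[rid])
    mirna_seqs = _hit_sequences(map_perfect(tags, mature_ref))
    other_seqs = _hit_sequences(map_perfect(tags, other_ref)) \
        if other_ref else set()

    category, source = {}, {}
    for tag in tags:
        seq = tag.sequence
        hits = {s: per_source.get(s, {}).get(seq) for s in per_source}
        cat, src = classify_tag(seq, hits, seq in mirna_seqs,
                                seq in other_seqs)
        category[seq] = cat
        source[seq] = src
    result = AnnotationResult(category=category, source=source)
    result.validate(tags)
    return result


def summarize_composition(annotations: AnnotationResult,
                          tags) -> pd.DataFrame:
    """Per-category unique and total (redundant) counts and percentages
    per library; unique/total sums are conserved by construction."""
    rows = {c: {"category": c, "unique_ck": 0, "unique_cd": 0,
                "total_ck": 0, "total_cd": 0} for c in CATEGORIES}
    for tag in tags:
        cat = annotations.category[tag.sequence]
        r = rows[cat]
        r["unique_ck"] += int(tag.count_ck > 0)
        r["unique_cd"] += int(tag.count_cd > 0)
        r["total_ck"] += tag.count_ck
        r["total_cd"] += tag.count_cd
    df = pd.DataFrame([rows[c] for c in CATEGORIES])
    for col in ("unique_ck", "unique_cd", "total_ck", "total_cd"):
        total = df[col].sum()
        df[f"pct_{col}"] = 100.0 * df[col] / total if total else 0.0
    return df
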