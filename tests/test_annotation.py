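"""Annotation: exact substring mapping, the single-category priority
rule, and composition bookkeeping."""

import itertools
import random

import pytest

from typhamir.annotation import (ReferenceSet, annotate_tags, classify_tag,
                                 map_perfect, summarize_composition)
from typhamir.preprocess import SmallRNATag


def _refset(source, **records_by_type):
    records, types = {}, {}
    for rna_type, seqs in records_by_type.items():
        for i, s in enumerate(seqs):
            rid = f"{source}_{rna_type}_{i}"
            records[rid] = s
            types[rid] = rna_type
    return ReferenceSet(name=source, source=source, records=records,
                        types=types)


class TestMapPerfect:
    def test_prefix_hit_offset_zero(self):
        hits = map_perfect(["ACGTACGT"], {"r1": "ACGTACGTTTTT"})
        assert ("ACGTACGT", "r1", 0) in hits

    def test_single_mismatch_no_hit(self):
        assert map_perfect(["ACGTACGA"], {"r1": "ACGTACGTTTTT"}) == []

    def test_matches_bruteforce_scan(self):
        rng = random.Random(4)
        ref = {f"r{i}": "".join(rng.choice("ACGT") for _ in range(300))
               for i in range(5)}
        tags = ["".join(rng.choice("ACGT") for _ in range(6))
                for _ in range(100)]
        # also plant guaranteed hits
        tags += [ref["r0"][10:30], ref["r3"][100:118]]
        expected = set()
        for t in tags:
            for rid, seq in ref.items():
                for off in range(len(seq) - len(t) + 1):
                    if seq[off:off + len(t)] == t:
                        expected.add((t, rid, off))
        assert set(map_perfect(tags, ref)) == expected


class TestPriorityRule:
    def test_ncrna_beats_mirna(self):
        cat, src = classify_tag("X", {"GenBank": {"rRNA"}}, True, False)
        assert (cat, src) == ("rRNA", "GenBank")

    def test_genbank_beats_rfam(self):
        cat, src = classify_tag("X", {"GenBank": {"tRNA"},
                                      "Rfam": {"rRNA"}}, False, False)
        assert (cat, src) == ("tRNA", "GenBank")

    def test_mirna_only(self):
        assert classify_tag("X", {}, True, False) == ("known_miRNA",
                                                      "none")

    def test_unannotated(self):
        assert classify_tag("X", {}, False, False) == ("unannotated",
                                                       "none")

    def test_priority_total_under_permutation(self):
        """Permuting the evaluation order of the hit sets never changes
        the assigned category."""
        hit_options = [None, {"rRNA"}, {"snoRNA"}, {"rRNA", "tRNA"}]
        for gb, rf, mi in itertools.product(hit_options, hit_options,
                                            (False, True)):
            hits = {"GenBank": gb, "Rfam": rf}
            baseline = classify_tag("X", hits, mi, False)
            for perm in itertools.permutations(hits.items()):
                assert classify_tag("X", dict(perm), mi, False) == baseline


class TestAnnotateAndSummarize:
    def _tags(self):
        return [SmallRNATag("ACGTACGTACGTACGTA", 2, 1),   # rRNA (GenBank)
                SmallRNATag("TTTTGGGGCCCCAAAAG", 1, 0),   # known miRNA
                SmallRNATag("GCGCGCGCATATATATC", 0, 3)]   # unannotated

    def _refs(self):
        genbank = _refset("GenBank", rRNA=["ACGTACGTACGTACGTACGTACG"])
        rfam = _refset("Rfam", tRNA=["ACGTACGTACGTACGTATTTTTT"])
        mature = {"mir1": "TTTTGGGGCCCCAAAAGGGGG",
                  "mir2": "ACGTACGTACGTACGTACG"}
        return [genbank, rfam], mature

    def test_single_assignment_and_priority(self):
        tags = self._tags()
        ncrna, mature = self._refs()
        ann = annotate_tags(tags, ncrna, mature)
        # first tag hits GenBank rRNA, Rfam tRNA and a mature miRNA:
        # the GenBank ncRNA wins
        assert ann.category[tags[0].sequence] == "rRNA"
        assert ann.source[tags[0].sequence] == "GenBank"
        assert ann.category[tags[1].sequence] == "known_miRNA"
        assert ann.category[tags[2].sequence] == "unannotated"

    def test_composition_conservation(self):
        tags = self._tags()
        ncrna, mature = self._refs()
        df = summarize_composition(annotate_tags(tags, ncrna, mature),
                                   tags)
        assert df["unique_ck"].sum() == sum(t.count_ck > 0 for t in tags)
        assert df["total_ck"].sum() == sum(t.count_ck for t in tags)
        assert df["total_cd"].sum() == sum(t.count_cd for t in tags)
        assert df["pct_total_ck"].sum() == pytest.approx(100.0, abs=0.01)

    def test_all_unannotated(self):
        tags = [SmallRNATag("GGGGGTTTTTCCCCCA", 1, 1)]
        df = summarize_composition(annotate_tags(tags, [], {}), tags)
        row = df[df.category == "unannotated"].iloc[0]
        assert row["pct_total_ck"] == 100.0


def test_planted_ncrna_share_recovered(sim, report):
    """At 30% planted ncRNA reads, the classified ncRNA share of clean
    reads lands within sampling error of the planted fraction."""
    comp = report.composition
    nc = comp[comp.category.isin(["rRNA", "tRNA", "snRNA", "snoRNA"])]
    clean_total = report.stats_ck.clean_reads + report.stats_cd.clean_reads
    share = (nc["total_ck"].sum() + nc["total_cd"].sum()) / clean_total
    planted = sim.truth.ncrna_fraction * 2 * 30_000 / clean_total
    sd = (planted * (1 - planted) / clean_total) ** 0.5
    assert abs(share - planted) <= max(3 * sd, 0.01)
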