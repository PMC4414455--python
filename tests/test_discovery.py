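"""miRNA discovery: mismatch-bounded conserved matching, cluster
quantification rules, hairpin-based novel prediction, 5p/3p pairing and
isomiR enumeration."""

import numpy as np
import pytest

from typhamir.discovery import (NovelParams, cluster_and_quantify,
                                detect_star, enumerate_isomirs,
                                find_precursor, match_conserved,
                                predict_novel, _novel_rule_ok)
from typhamir.preprocess import SmallRNATag
from typhamir.synthetic import gen_premirna, make_truth_set, star_sequence

REF = {"kno-miR900": "TGACAGAAGAGAGTGAGCACA"}


def _mutate(seq, positions):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[p]]
    return "".join(s)


class TestMatchConserved:
    def test_identical_is_zero_mismatch(self):
        hits = match_conserved([REF["kno-miR900"]], REF)
        assert hits[REF["kno-miR900"]] == ("kno-miR900", 0)

    def test_two_substitutions_hit(self):
        tag = _mutate(REF["kno-miR900"], [5, 12])
        assert match_conserved([tag], REF)[tag] == ("kno-miR900", 2)

    def test_three_substitutions_no_hit(self):
        tag = _mutate(REF["kno-miR900"], [5, 12, 18])
        assert match_conserved([tag], REF) == {}

    def test_length_difference_bound(self):
        short = REF["kno-miR900"][2:-1]     # 3 nt shorter: rejected
        assert match_conserved([short], REF) == {}
        ok = REF["kno-miR900"][1:-1]        # 2 nt shorter: slid core hit
        assert match_conserved([ok], REF)[ok][1] == 0

    def test_best_hit_tie_break_by_name(self):
        ref = {"b-mir": "AAAAGGGGCCCCTTTTAAAAG",
               "a-mir": "AAAAGGGGCCCCTTTTAAAAG"}
        tag = "AAAAGGGGCCCCTTTTAAAAG"
        assert match_conserved([tag], ref)[tag][0] == "a-mir"


class TestClusterAndQuantify:
    def test_dominant_representative_and_sum(self):
        tags = {"A" * 21: SmallRNATag("A" * 21, 7, 3),
                "A" * 20 + "G": SmallRNATag("A" * 20 + "G", 2, 1)}
        recs = cluster_and_quantify({"mir": list(tags)}, tags, "conserved")
        assert recs[0].representative_seq == "A" * 21
        assert (recs[0].expr_ck, recs[0].expr_cd) == (9, 4)

    def test_representative_tie_lexicographic(self):
        tags = {"C" * 21: SmallRNATag("C" * 21, 5, 0),
                "A" * 21: SmallRNATag("A" * 21, 5, 0)}
        recs = cluster_and_quantify({"mir": list(tags)}, tags, "conserved")
        assert recs[0].representative_seq == "A" * 21

    def test_novel_rule_excludes_middle_substitution(self):
        rep = "TGACAGAAGAGAGTGAGCACA"
        member = _mutate(rep, [10])
        assert not _novel_rule_ok(member, rep)

    def test_novel_rule_allows_terminal_trim(self):
        rep = "TGACAGAAGAGAGTGAGCACA"
        assert _novel_rule_ok(rep[:-2], rep)       # 2-nt 3' trim
        assert _novel_rule_ok(rep[1:], rep)        # 1-nt 5' trim
        assert not _novel_rule_ok(rep[4:], rep)    # 4 nt exceeds terminal

    def test_expression_permutation_invariant(self):
        tags = {"A" * 21: SmallRNATag("A" * 21, 7, 3),
                "G" + "A" * 20: SmallRNATag("G" + "A" * 20, 1, 5),
                "A" * 20 + "C": SmallRNATag("A" * 20 + "C", 2, 2)}
        orders = [list(tags), list(reversed(list(tags)))]
        results = [cluster_and_quantify({"m": o}, tags, "novel")[0]
                   for o in orders]
        assert results[0].expr_ck == results[1].expr_ck
        assert results[0].representative_seq == \
            results[1].representative_seq


class TestNovelPrediction:
    def test_planted_hairpin_recovered(self, rng):
        p = gen_premirna(35, 10, 1, rng)
        p.name = "px"
        flank_l = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        flank_r = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        tx = {"u1": flank_l + p.sequence + flank_r}
        tags = [SmallRNATag(p.mature, 12, 8)]
        cands, recs = predict_novel(tags, tx)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.representative_seq == p.mature
        assert (rec.expr_ck, rec.expr_cd) == (12, 8)
        c = rec.precursor
        assert c.mfe <= -18.0 and c.mfei <= -0.5
        assert 68 <= len(c.sequence) <= 300
        assert p.mature in c.sequence

    def test_unstructured_background_yields_nothing(self, rng):
        tx = {"bg": "".join(np.array(list("ACGT"))[rng.integers(0, 4,
                                                                1000)])}
        tag_seq = tx["bg"][300:321]
        _, recs = predict_novel([SmallRNATag(tag_seq, 50, 50)], tx)
        assert recs == []

    def test_mature_straddling_loop_rejected(self, rng):
        """A tag centered on the hairpin loop is not a mature miRNA."""
        p = gen_premirna(30, 8, 0, rng)
        straddle = p.sequence[20:41]  # covers the loop (30..38)
        tx = {"u1": p.sequence}
        _, recs = predict_novel([SmallRNATag(straddle, 30, 30)], tx)
        assert recs == []

    def test_accepted_candidates_satisfy_criteria_on_recheck(self, sim,
                                                             report):
        from typhamir.discovery import _check_candidate
        params = NovelParams()
        for rec in report.novel:
            c = rec.precursor
            res = _check_candidate(c.sequence, *c.mature_span, params)
            assert res is not None
            fold, arm = res
            assert arm == c.arm and fold.mfe == c.mfe


class TestStarDetection:
    def _setup(self, rng, star_counts=(5, 5)):
        truth = make_truth_set(31, n_conserved=0, n_novel=1)
        p = truth.premirnas[0]
        star = star_sequence(p)
        tx = {"u1": p.sequence}
        tags = [SmallRNATag(p.mature, 40, 40)]
        if star_counts:
            tags.append(SmallRNATag(star, *star_counts))
        _, recs = predict_novel(tags, tx)
        assert len(recs) == 1
        return recs[0], tags, star

    def test_pair_detected_with_reads_on_both_arms(self, rng):
        rec, tags, star = self._setup(rng)
        assert detect_star(rec.precursor, tags) == star

    def test_no_pair_with_one_arm_only(self, rng):
        rec, tags, _ = self._setup(rng, star_counts=None)
        assert detect_star(rec.precursor, tags) is None

    def test_large_overhang_rejected(self, rng):
        rec, tags, star = self._setup(rng, star_counts=None)
        pos = rec.precursor.sequence.find(star)
        shifted = rec.precursor.sequence[pos + 5:pos + 5 + len(star)]
        tags.append(SmallRNATag(shifted, 5, 5))
        assert detect_star(rec.precursor, tags) is None


class TestIsomirs:
    def _record(self, rng):
        p = gen_premirna(35, 10, 0, rng)
        p.name = "px"
        tx = {"u1": p.sequence}
        canonical = SmallRNATag(p.mature, 50, 40)
        trimmed5 = SmallRNATag(p.mature[1:], 7, 3)
        ext3 = SmallRNATag(
            p.sequence[p.mature_start:p.mature_end + 2], 4, 6)
        tags = [canonical, trimmed5, ext3]
        _, recs = predict_novel(tags, tx)
        assert len(recs) == 1
        return recs[0], tags, p

    def test_offsets_and_counts(self, rng):
        rec, tags, p = self._record(rng)
        isos = {i.sequence: i for i in enumerate_isomirs(rec, tags)}
        assert len(isos) == 3
        canonical = isos[p.mature]
        assert (canonical.offset_5p, canonical.offset_3p) == (0, 0)
        assert canonical.is_canonical
        assert (isos[p.mature[1:]].offset_5p,
                isos[p.mature[1:]].offset_3p) == (1, 0)
        ext = isos[p.sequence[p.mature_start:p.mature_end + 2]]
        assert (ext.offset_5p, ext.offset_3p) == (0, -2)
        assert (ext.count_ck, ext.count_cd) == (4, 6)

    def test_requires_precursor(self, rng):
        from typhamir.discovery import MatureMiRNARecord
        rec = MatureMiRNARecord(name="x", mirna_class="novel",
                                representative_seq="A" * 21)
        with pytest.raises(ValueError):
            enumerate_isomirs(rec, [])


def test_find_precursor_prefers_sense_locus(rng):
    p = gen_premirna(32, 9, 0, rng)
    tx = {"u1": "ACGT" * 30 + p.sequence + "TGCA" * 30}
    cand = find_precursor(p.mature, tx)
    assert cand is not None and cand.strand == "+"
    assert p.mature in cand.sequence
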