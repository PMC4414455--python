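"""Read cleaning and tag collapsing: rule-by-rule behavior, count
conservation and idempotence."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from typhamir.preprocess import (CleanStats, SmallRNATag, clean_library,
                                 collapse_tags, first_base_bias,
                                 length_distribution, trim_adapter)
from typhamir.synthetic import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5

AD3 = DEFAULT_ADAPTER3
AD5 = DEFAULT_ADAPTER5
SEQ20 = "ACGTACGTACGTACGTACGT"

dna = st.text(alphabet="ACGT", min_size=15, max_size=30)


class TestTrimAdapter:
    def test_exact_adapter_appended(self):
        assert trim_adapter(SEQ20 + AD3, AD3) == SEQ20

    def test_read_equal_to_adapter_is_empty_insert(self):
        assert trim_adapter(AD3, AD3) is None

    def test_no_adapter_occurrence(self):
        assert trim_adapter("ACGT" * 10, AD3) is None

    def test_partial_adapter_at_read_end(self):
        assert trim_adapter(SEQ20 + AD3[:6], AD3) == SEQ20

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter(SEQ20, "ACGTA")

    @given(insert=dna)
    def test_roundtrip_insert_recovered(self, insert):
        read = insert + AD3
        trimmed = trim_adapter(read, AD3)
        # the insert may itself contain the adapter probe; the trim is
        # then left-most, hence a prefix of the planted insert
        assert trimmed is not None and insert.startswith(trimmed)


class TestCleanLibrary:
    def _clean_one(self, insert, qual=None):
        read = insert + AD3
        reads = [(read, qual or "I" * len(read))]
        return clean_library(reads)

    def test_14nt_insert_removed_too_short(self):
        inserts, stats = self._clean_one("ACGTCGTAGCTAGC")
        assert not inserts and stats.removed_by_reason["too_short"] == 1

    def test_31nt_insert_removed_too_long(self):
        inserts, stats = self._clean_one("CGTA" * 7 + "CGT")
        assert not inserts and stats.removed_by_reason["too_long"] == 1

    def test_polya_insert_removed(self):
        inserts, stats = self._clean_one("A" * 16)
        assert not inserts and stats.removed_by_reason["polya"] == 1

    def test_low_quality_removed_first(self):
        read = "A" * 16 + AD3
        _, stats = clean_library([(read, "#" * len(read))])
        assert stats.removed_by_reason["low_quality"] == 1
        assert stats.removed_by_reason["polya"] == 0

    def test_contaminant_5p_removed(self):
        read = AD5[-8:] + "CGTACGTACGTAC" + AD3
        _, stats = clean_library([(read, "I" * len(read))])
        assert stats.removed_by_reason["contaminant_5p"] == 1

    def test_count_conservation(self):
        reads = [SEQ20 + AD3, AD3, "ACGT" * 12, "A" * 16 + AD3]
        inserts, stats = clean_library(reads)
        stats.validate()
        assert stats.raw_reads == 4 and stats.clean_reads == len(inserts)

    def test_cleaning_is_idempotent(self):
        reads = [SEQ20 + AD3, "TGCATGCATGCATGCAT" + AD3]
        inserts, _ = clean_library(reads)
        again, stats = clean_library([i + AD3 for i in inserts])
        assert again == inserts
        assert sum(stats.removed_by_reason.values()) == 0


class TestCollapseTags:
    def test_explicit_counts(self):
        tags = collapse_tags(["AAGCT", "AAGCT"], ["AAGCT", "GGCAT"])
        assert [(t.sequence, t.count_ck, t.count_cd) for t in tags] == \
            [("AAGCT", 2, 1), ("GGCAT", 0, 1)]

    def test_empty_inputs(self):
        assert collapse_tags([], []) == []

    @given(ck=st.lists(dna, max_size=30), cd=st.lists(dna, max_size=30))
    def test_count_conservation_property(self, ck, cd):
        tags = collapse_tags(ck, cd)
        assert sum(t.count_ck for t in tags) == len(ck)
        assert sum(t.count_cd for t in tags) == len(cd)
        assert len({t.sequence for t in tags}) == len(tags)

    def test_deterministic_order(self):
        tags = collapse_tags(["CCC" * 5, "AAA" * 5], ["AAA" * 5,
                                                      "CCC" * 5])
        # equal totals: lexicographic tie-break
        assert [t.sequence for t in tags] == ["AAA" * 5, "CCC" * 5]


class TestSummaries:
    def test_single_tag_distribution(self):
        tags = [SmallRNATag("A" * 21, 5, 0)]
        df = length_distribution(tags, "total")
        assert df.loc[df.length == 21, "pct_ck"].iloc[0] == 100.0

    def test_total_vs_unique_mode(self):
        tags = [SmallRNATag("G" * 21, 3, 3), SmallRNATag("C" * 24, 1, 1)]
        total = length_distribution(tags, "total")
        uniq = length_distribution(tags, "unique")
        assert list(total["pct_ck"]) == [75.0, 25.0]
        assert list(uniq["pct_ck"]) == [50.0, 50.0]

    def test_percentages_sum_to_100(self, sim):
        from typhamir.preprocess import collapse_tags as ct
        inserts_ck, _ = clean_library(sim.lib_ck.reads)
        inserts_cd, _ = clean_library(sim.lib_cd.reads)
        df = length_distribution(ct(inserts_ck, inserts_cd), "total")
        assert df["pct_ck"].sum() == pytest.approx(100.0, abs=0.01)
        assert df["pct_cd"].sum() == pytest.approx(100.0, abs=0.01)

    def test_first_base_single_tag(self):
        df = first_base_bias([SmallRNATag("T" + "G" * 20, 1, 0)])
        assert df.loc[df.length == 21, "T"].iloc[0] == 1.0

    def test_first_base_even_split_and_row_sums(self):
        tags = [SmallRNATag("T" + "A" * 20, 1, 0),
                SmallRNATag("C" + "A" * 20, 1, 0)]
        df = first_base_bias(tags)
        row = df[df.length == 21].iloc[0]
        assert row["T"] == 0.5 and row["C"] == 0.5
        assert row[list("ACGT")].sum() == pytest.approx(1.0)

    def test_empty_length_class_omitted(self):
        df = first_base_bias([SmallRNATag("T" * 21, 1, 0)])
        assert set(df["length"]) == {21}
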