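"""Synthetic-data generator: construction invariants, count model,
adapter layout, and seed determinism."""

import numpy as np
import pytest

from typhamir.fold import fold_rna
from typhamir.preprocess import clean_library
from typhamir.synthetic import (DEFAULT_ADAPTER3, TruthSet, gen_libraries,
                                gen_premirna, gen_transcriptome,
                                make_truth_set, simulate, star_sequence,
                                TargetSpec)


def test_perfect_hairpin_construction(rng):
    """A bulge-free 30/8 hairpin is 68 nt and folds with >= 28 pairs."""
    p = gen_premirna(stem_len=30, loop_len=8, n_bulges=0, rng=rng)
    assert len(p.sequence) == 68
    assert p.mature in p.sequence
    assert fold_rna(p.sequence).n_pairs >= 28


def test_bulged_hairpin_length(rng):
    p = gen_premirna(stem_len=30, loop_len=8, n_bulges=2, rng=rng)
    assert len(p.sequence) == 70
    assert p.sequence[p.mature_start:p.mature_end] == p.mature


def test_generated_hairpins_fold_negative(rng):
    """Every generated precursor has a negative-MFE fold."""
    for _ in range(30):
        p = gen_premirna(stem_len=int(rng.integers(30, 46)),
                         loop_len=int(rng.integers(8, 21)),
                         n_bulges=int(rng.integers(0, 3)), rng=rng)
        assert fold_rna(p.sequence).mfe < 0


@pytest.mark.parametrize("stem,loop,bulges", [
    (18, 8, 0),     # 44 nt, too short
    (130, 8, 0),    # 268 nt, too long
])
def test_premirna_length_bounds_rejected(stem, loop, bulges, rng):
    with pytest.raises(ValueError):
        gen_premirna(stem, loop, bulges, rng)


def test_truth_set_invariants():
    truth = make_truth_set(5)
    truth.validate()
    assert all(68 <= len(p.sequence) <= 255 for p in truth.premirnas)
    assert all(v > 0 for pair in truth.mirna_abundance.values()
               for v in pair)
    for name, (ck, cd) in truth.mirna_abundance.items():
        assert truth.fold_changes[name] == pytest.approx(np.log2(cd / ck))


def test_transcriptome_bookkeeping(rng):
    truth = make_truth_set(6, n_conserved=3, n_novel=2)
    specs = [TargetSpec(truth.premirnas[0].name, 1, []),
             TargetSpec(truth.premirnas[1].name, 2, [(16, "mm")])]
    records, embedded, sites = gen_transcriptome(
        50, truth.premirnas, specs, rng)
    assert len(records) == 50 + 5 + 3
    assert len(set(records)) == len(records)
    assert all(300 <= len(s) <= 2000 for k, s in records.items()
               if k.startswith("unigene_bg"))
    # precursors embedded verbatim at the recorded coordinates
    for _, row in embedded.iterrows():
        pre = next(p for p in truth.premirnas if p.name == row["premirna"])
        assert records[row["unigene"]][row["start"]:row["end"]] == \
            pre.sequence


def test_transcriptome_unknown_target_spec_rejected(rng):
    truth = make_truth_set(6, n_conserved=2, n_novel=1)
    with pytest.raises(ValueError):
        gen_transcriptome(5, truth.premirnas,
                          [TargetSpec("nonexistent", 1, [])], rng)


def test_condition_ratio_recovered(rng):
    """One miRNA at mean 100 (CK) vs 400 (Cd) with dispersion -> 0:
    observed ratio within 3 binomial SDs."""
    p = gen_premirna(30, 8, 0, rng)
    p.name = "m1"
    truth = TruthSet(premirnas=[p], mirna_abundance={"m1": (100.0, 400.0)},
                     fold_changes={"m1": 2.0}, ncrna_fraction=0.0,
                     seed=42, dispersion=0.0, isomir_fraction=0.0,
                     bad_read_fraction=0.0, star_fraction=0.0)
    lib_ck, lib_cd, counts = gen_libraries(truth, depth=10_000, rng=rng)
    ck = int(counts.query("library == 'CK'")["count"].iloc[0])
    cd = int(counts.query("library == 'Cd'")["count"].iloc[0])
    assert abs(ck - 100) <= 3 * np.sqrt(100)
    assert abs(cd - 400) <= 3 * np.sqrt(400)


def test_reads_carry_adapter_prefix(rng):
    truth = make_truth_set(7, n_conserved=2, n_novel=1)
    truth.bad_read_fraction = 0.0
    lib_ck, _, _ = gen_libraries(truth, depth=500, rng=rng)
    for seq, _ in lib_ck.reads[:200]:
        # insert + a prefix of the 3' adapter must be present
        assert DEFAULT_ADAPTER3[:8] in seq or \
            any(seq.endswith(DEFAULT_ADAPTER3[:k]) for k in range(6, 9))


def test_bad_read_fraction_removed_by_cleaning(rng):
    truth = make_truth_set(8, n_conserved=2, n_novel=1)
    truth.bad_read_fraction = 0.1
    truth.ncrna_fraction = 0.0
    lib_ck, _, _ = gen_libraries(truth, depth=10_000, rng=rng)
    _, stats = clean_library(lib_ck.reads)
    removed = stats.raw_reads - stats.clean_reads
    assert 850 <= removed <= 1150  # ~1000 of 10^4 planted bad reads


def test_star_sequence_geometry():
    truth = make_truth_set(9, n_conserved=2, n_novel=1)
    p = truth.premirnas[0]
    star = star_sequence(p)
    assert star is not None
    assert star in p.sequence
    # star lies on the opposite arm
    pos = p.sequence.find(star)
    if p.arm == "5p":
        assert pos >= p.mature_end - 3
    else:
        assert pos + len(star) <= p.mature_start + 3


def test_simulation_is_seed_deterministic(tmp_path):
    a = simulate(seed=77, outdir=tmp_path / "a", depth=2_000,
                 n_background=5)
    b = simulate(seed=77, outdir=tmp_path / "b", depth=2_000,
                 n_background=5)
    for key in a.paths:
        assert a.paths[key].read_bytes() == b.paths[key].read_bytes(), key
    c = simulate(seed=78, outdir=tmp_path / "c", depth=2_000,
                 n_background=5)
    assert a.paths["reads_ck"].read_bytes() != \
        c.paths["reads_ck"].read_bytes()


def test_library_alphabet(sim):
    sim.lib_ck.validate()
    sim.lib_cd.validate()
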