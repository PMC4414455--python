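"""Ground-truthed synthetic inputs for the small-RNA pipeline.

Emulates the structure of a two-condition plant small-RNA sequencing
experiment: a control (CK) and a cadmium-treated (Cd) adapter-ligated
library of 18-30 nt reads drawn from planted pre-miRNA hairpins (with
isomiR variation), degradation fragments of non-coding RNAs, random
background, and a small fraction of deliberately bad reads; plus the
reference files the pipeline consumes (ncRNA sets, a known-mature miRNA
FASTA, and a transcriptome of unigenes embedding precursors and target
sites). Per-miRNA counts are negative-binomial with condition-specific
means; Poisson is the dispersion -> 0 limit.

Every random draw flows through one `numpy.random.Generator`, so a given
seed yields byte-identical FASTA/FASTQ/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import revcomp, write_fasta, write_fastq

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"        # Illumina TruSeq small-RNA
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
POST_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTG"
READ_LENGTH = 49


@dataclass
class PlantedPremiRNA:
    """A planted hairpin precursor with its mature miRNA coordinates
    (0-based, half-open) and arm ('5p' or '3p')."""

    name: str
    sequence: str
    mature_start: int
    mature_end: int
    arm: str
    conserved: bool = False
    known_name: str | None = None

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_start:self.mature_end]


@dataclass
class TruthSet:
    premirnas: list[PlantedPremiRNA]
    mirna_abundance: dict[str, tuple[float, float]]  # name -> (CK, Cd) mean
    fold_changes: dict[str, float]                   # name -> true log2 Cd/CK
    ncrna_fraction: float
    seed: int
    dispersion: float = 0.01
    isomir_fraction: float = 0.2
    bad_read_fraction: float = 0.06
    star_fraction: float = 0.05

    def validate(self) -> None:
        for p in self.premirnas:
            if p.mature not in p.sequence:
                raise AssertionError(f"{p.name}: mature not in precursor")
            if not 68 <= len(p.sequence) <= 255:
                raise AssertionError(f"{p.name}: precursor length "
                                     f"{len(p.sequence)} outside [68, 255]")
        for name, (ck, cd) in self.mirna_abundance.items():
            if ck <= 0 or cd <= 0:
                raise AssertionError(f"{name}: non-positive abundance mean")


@dataclass
class SyntheticLibrary:
    """Simulated reads for one condition; reads are (sequence, quality)."""

    reads: list[tuple[str, str]]
    condition_label: str

    def validate(self) -> None:
        for seq, _ in self.reads:
            if any(c not in "ACGTN" for c in seq):
                raise AssertionError("read outside {A,C,G,T,N}")


def _random_seq(rng, n: int, gc_bias: float = 0.0) -> str:
    p_gc = 0.25 + gc_bias / 2
    p_at = 0.25 - gc_bias / 2
    idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
    return "".join(np.array(list("ACGT"))[idx])


def gen_premirna(stem_len: int, loop_len: int, n_bulges: int, rng,
                 mature_len: int | None = None,
                 arm: str | None = None) -> PlantedPremiRNA:
    """Build a stem + loop + reverse-complement-of-stem hairpin with
    `n_bulges` single-nucleotide insertions placed in the arm opposite the
    mature miRNA, which is 20-22 nt and lies wholly within one arm.

    Raises ValueError when the total length falls outside [68, 255].
    """
    if stem_len < 18:
        raise ValueError("stem_len must be >= 18")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    total = 2 * stem_len + loop_len + n_bulges
    if not 68 <= total <= 255:
        raise ValueError(f"total length {total} outside [68, 255]")
    if mature_len is None:
        mature_len = int(rng.integers(20, 23))
    if not 20 <= mature_len <= 22 or mature_len > stem_len - 2:
        raise ValueError("mature must be 20-22 nt and fit in the stem")
    if arm is None:
        arm = "5p" if rng.random() < 0.5 else "3p"

    stem = list(_random_seq(rng, stem_len, gc_bias=0.15))
    # mature position within the stem (leaving >= 1 nt margin each side)
    m_off = int(rng.integers(1, stem_len - mature_len))
    # plant a 5'-U bias on the mature first base (rendered T in DNA space)
    if rng.random() < 0.7:
        if arm == "5p":
            stem[m_off] = "T"
        else:
            # mature comes from the reverse complement arm: its first base
            # maps to the stem base complementary at the mirrored offset
            stem[stem_len - 1 - m_off] = "A"
    stem = "".join(stem)
    loop = _random_seq(rng, loop_len)
    arm5, arm3 = stem, revcomp(stem)

    if arm == "5p":
        mature_start = m_off
    else:
        mature_start = len(arm5) + loop_len + m_off

    if n_bulges:
        if arm == "5p":  # bulges in 3' arm
            lo = len(arm5) + loop_len
            positions = sorted(rng.integers(1, stem_len - 1,
                                            size=n_bulges).tolist())
            a3 = list(arm3)
            for shift, pos in enumerate(positions):
                a3.insert(pos + shift, str(_random_seq(rng, 1)))
            arm3 = "".join(a3)
        else:            # bulges in 5' arm; mature coords shift right
            positions = sorted(rng.integers(1, stem_len - 1,
                                            size=n_bulges).tolist())
            a5 = list(arm5)
            for shift, pos in enumerate(positions):
                a5.insert(pos + shift, str(_random_seq(rng, 1)))
            arm5 = "".join(a5)
            mature_start += n_bulges

    sequence = arm5 + loop + arm3
    return PlantedPremiRNA(name="", sequence=sequence,
                           mature_start=mature_start,
                           mature_end=mature_start + mature_len, arm=arm)


@dataclass
class TargetSpec:
    """A target site to embed: `pattern` lists (miRNA position 1-based
    from the 5' end, 'mm' | 'gu') modifications of the perfect site."""

    mirna_name: str
    n_sites: int = 1
    pattern: list[tuple[int, str]] = field(default_factory=list)


def build_target_site(mature: str, pattern: list[tuple[int, str]],
                      rng) -> str:
    """Reverse-complement site for `mature` with the requested mismatch /
    G:U wobble pattern applied (positions 1-based on the miRNA)."""
    site = list(revcomp(mature))
    L = len(mature)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for pos, kind in pattern:
        if not 1 <= pos <= L:
            raise ValueError("pattern position outside miRNA")
        b = mature[pos - 1]
        idx = L - pos  # miRNA position pos pairs the site base at idx
        if kind == "gu":
            if b == "G":
                site[idx] = "T"
            elif b == "T":
                site[idx] = "G"
            else:
                raise ValueError(f"G:U impossible at miRNA position {pos} "
                                 f"(base {b})")
        elif kind == "mm":
            choices = [c for c in "ACGT"
                       if c != comp[b] and {b, c} not in ({"G", "T"},)]
            site[idx] = choices[int(rng.integers(len(choices)))]
        else:
            raise ValueError(f"unknown pattern kind {kind!r}")
    return "".join(site)


def gen_transcriptome(n_background: int, premirnas: list[PlantedPremiRNA],
                      target_specs: list[TargetSpec], rng,
                      embed: list[str] | None = None):
    """Synthetic unigene set: random background transcripts of 300-2000 nt,
    transcripts embedding precursor hairpins verbatim, and transcripts
    embedding reverse-complement target sites with specified patterns.

    Returns (records, embedded_df, sites_df): `records` is an ordered
    {unigene_id: sequence}; the two data frames are truth annotations with
    0-based half-open coordinates.
    """
    by_name = {p.name: p for p in premirnas}
    records: dict[str, str] = {}
    embedded_rows, site_rows = [], []

    def add(uid: str, seq: str):
        if uid in records:
            raise ValueError(f"duplicate unigene id {uid!r}")
        records[uid] = seq

    for i in range(n_background):
        n = int(rng.integers(300, 2001))
        add(f"unigene_bg_{i:04d}", _random_seq(rng, n))

    embed_names = embed if embed is not None else [p.name for p in premirnas]
    for name in embed_names:
        p = by_name[name]
        left = _random_seq(rng, int(rng.integers(100, 401)))
        right = _random_seq(rng, int(rng.integers(100, 401)))
        uid = f"unigene_pre_{name}"
        add(uid, left + p.sequence + right)
        embedded_rows.append({"unigene": uid, "premirna": name,
                              "start": len(left),
                              "end": len(left) + len(p.sequence)})

    for spec in target_specs:
        if spec.mirna_name not in by_name:
            raise ValueError(f"target spec refers to unknown miRNA "
                             f"{spec.mirna_name!r}")
        mature = by_name[spec.mirna_name].mature
        for k in range(spec.n_sites):
            site = build_target_site(mature, spec.pattern, rng)
            left = _random_seq(rng, int(rng.integers(150, 601)))
            right = _random_seq(rng, int(rng.integers(150, 601)))
            uid = f"unigene_tgt_{spec.mirna_name}_{k}"
            add(uid, left + site + right)
            site_rows.append({"unigene": uid, "mirna": spec.mirna_name,
                              "start": len(left),
                              "end": len(left) + len(site),
                              "pattern": ";".join(f"{p}{k_}" for p, k_
                                                  in spec.pattern)})
    embedded_df = pd.DataFrame(embedded_rows,
                               columns=["unigene", "premirna", "start",
                                        "end"])
    sites_df = pd.DataFrame(site_rows, columns=["unigene", "mirna", "start",
                                                "end", "pattern"])
    return records, embedded_df, sites_df


def _nb_counts(rng, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion < 1e-9:
        return int(rng.poisson(mean))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return int(rng.poisson(lam))


def _isomir_variant(p: PlantedPremiRNA, rng) -> str:
    """A terminal trim/extension variant (1-3 nt per end) of the mature,
    taken from the precursor so extensions have real flanking sequence."""
    for _ in range(10):
        off5 = int(rng.integers(-3, 4))
        off3 = int(rng.integers(-3, 4))
        if off5 == 0 and off3 == 0:
            continue
        start = p.mature_start + off5
        end = p.mature_end - off3
        if 0 <= start < end <= len(p.sequence) and 15 <= end - start <= 30:
            return p.sequence[start:end]
    return p.mature


def star_sequence(p: PlantedPremiRNA, overhang: int = 2) -> str | None:
    """Partner-arm (star) sequence of a planted precursor under the
    standard Dicer duplex geometry (2-nt 3' overhangs), derived from the
    precursor's own MFE fold."""
    from .fold import fold_rna

    pt = fold_rna(p.sequence).pair_table()
    m0, m1 = p.mature_start, p.mature_end

    def partner_near(i):
        for d in range(m1 - m0):
            for k in (i - d, i + d):
                if m0 <= k < m1 and pt[k] >= 0:
                    return pt[k] + (k - i)
        return None

    a = partner_near(m1 - 1 - overhang)
    b = partner_near(m0)
    if a is None or b is None:
        return None
    lo = max(0, min(a, b))
    hi = min(len(p.sequence), max(a, b) + overhang + 1)
    if hi - lo < 15:
        return None
    return p.sequence[lo:hi]


def gen_libraries(truth: TruthSet, depth: int,
                  adapter3: str = DEFAULT_ADAPTER3,
                  rng=None, ncrna_refs=None,
                  adapter5: str = DEFAULT_ADAPTER5,
                  read_length: int = READ_LENGTH):
    """Simulate the CK and Cd libraries.

    `depth` is the nominal library size: ncRNA/bad/background read
    numbers are fractions of it, while per-miRNA counts are absolute
    negative-binomial draws from the truth means (so a library can
    exceed `depth` when the planted means dominate).

    Returns (lib_ck, lib_cd, counts_df) where counts_df records the exact
    sampled per-miRNA read counts (canonical + isomiR) per library --
    the ground truth that a lossless pipeline should recover.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    ncrna_pool: list[str] = []
    if ncrna_refs:
        for refset in ncrna_refs:
            ncrna_pool.extend(refset.records.values())

    stars = {p.name: star_sequence(p) for p in truth.premirnas} \
        if truth.star_fraction > 0 else {}
    count_rows = []
    libs = []
    for cond_idx, cond in enumerate(("CK", "Cd")):
        inserts: list[tuple[str, str]] = []  # (sequence, kind)
        for p in truth.premirnas:
            mean = truth.mirna_abundance[p.name][cond_idx]
            count = _nb_counts(rng, mean, truth.dispersion)
            n_iso = int(rng.binomial(count, truth.isomir_fraction)) \
                if count else 0
            star = stars.get(p.name)
            n_star = int(rng.binomial(count, truth.star_fraction)) \
                if count and star else 0
            count_rows.append({"mirna": p.name, "library": cond,
                               "count": count, "isomir_count": n_iso,
                               "star_count": n_star})
            inserts.extend([(p.mature, "mirna")] * (count - n_iso))
            for _ in range(n_iso):
                inserts.append((_isomir_variant(p, rng), "mirna"))
            # star-strand reads are additional, lower-abundance species
            inserts.extend([(star, "mirna_star")] * n_star)
        n_ncrna = int(round(truth.ncrna_fraction * depth)) \
            if ncrna_pool else 0
        for _ in range(n_ncrna):
            ref = ncrna_pool[int(rng.integers(len(ncrna_pool)))]
            ln = int(rng.integers(18, 29))
            start = int(rng.integers(0, max(1, len(ref) - ln)))
            inserts.append((ref[start:start + ln], "ncrna"))
        n_bad = int(round(truth.bad_read_fraction * depth))
        n_back = max(0, depth - len(inserts) - n_bad)
        for _ in range(n_back):
            inserts.append((_random_seq(rng, int(rng.integers(18, 29))),
                            "background"))
        for _ in range(n_bad):
            kind = ("no_insert", "polya", "too_short", "low_quality",
                    "contaminant_5p")[int(rng.integers(5))]
            if kind == "no_insert":
                inserts.append(("", "bad"))
            elif kind == "polya":
                inserts.append(("A" * int(rng.integers(18, 25)), "bad"))
            elif kind == "too_short":
                inserts.append((_random_seq(rng, int(rng.integers(8, 13))),
                                "bad"))
            elif kind == "low_quality":
                inserts.append((_random_seq(rng, int(rng.integers(18, 25))),
                                "bad_lowq"))
            else:
                inserts.append((adapter5[-8:] + _random_seq(rng, 13), "bad"))

        order = rng.permutation(len(inserts))
        reads = []
        for idx in order:
            seq, kind = inserts[idx]
            read = (seq + adapter3 + POST_ADAPTER)[:read_length]
            read = read + "A" * (read_length - len(read))
            if kind == "bad_lowq":
                qual = list("I" * read_length)
                low = rng.choice(read_length,
                                 size=max(1, read_length * 2 // 5),
                                 replace=False)
                for q in low:
                    qual[q] = "#"
                qual = "".join(qual)
            else:
                qual = "I" * read_length
            reads.append((read, qual))
        libs.append(SyntheticLibrary(reads=reads, condition_label=cond))

    counts_df = pd.DataFrame(count_rows)
    return libs[0], libs[1], counts_df


def make_truth_set(seed: int, n_conserved: int = 12, n_novel: int = 8,
                   ncrna_fraction: float = 0.30, dispersion: float = 0.01,
                   isomir_fraction: float = 0.2,
                   bad_read_fraction: float = 0.06) -> TruthSet:
    """Planted miRNA population mirroring the study's qualitative findings:
    conserved miRNAs span a wide abundance range with a few modest (~1.65x)
    Cd-responsive members; novel miRNAs are lower-abundance with stronger
    (5x) responses; a few members are effectively library-specific."""
    rng = np.random.default_rng(seed)
    premirnas: list[PlantedPremiRNA] = []
    for i in range(n_conserved + n_novel):
        conserved = i < n_conserved
        for _ in range(50):
            try:
                p = gen_premirna(stem_len=int(rng.integers(30, 46)),
                                 loop_len=int(rng.integers(8, 21)),
                                 n_bulges=int(rng.integers(0, 3)), rng=rng)
                break
            except ValueError:
                continue
        if conserved:
            p.name = f"con-miR{i + 1:03d}"
            p.conserved = True
            p.known_name = f"kno-miR{i + 1:03d}"
        else:
            p.name = f"nov-mir{i - n_conserved + 1:03d}"
        premirnas.append(p)

    abundance: dict[str, tuple[float, float]] = {}
    fold: dict[str, float] = {}
    for i, p in enumerate(premirnas):
        if p.conserved:
            j = i
            if j < 4:          # modest down-regulation, mid abundance
                ck = float(10 ** rng.uniform(2.4, 2.9))
                cd = ck / 1.65
            elif j == 4:       # effectively Cd-specific
                ck, cd = 0.05, float(rng.uniform(50, 120))
            elif j == 5:       # effectively CK-specific
                ck, cd = float(rng.uniform(50, 120)), 0.05
            elif j < 8:        # dominant, stable expressors
                ck = float(10 ** rng.uniform(3.2, 3.7))
                cd = ck
            else:
                ck = float(10 ** rng.uniform(1.3, 2.8))
                cd = ck
        else:
            j = i - n_conserved
            if j < 2:          # strong up-regulation
                ck = float(rng.uniform(30, 120))
                cd = ck * 5.0
            elif j < 5:        # strong down-regulation
                ck = float(rng.uniform(150, 600))
                cd = ck / 5.0
            elif j == 5:       # Cd-specific novel
                ck, cd = 0.05, float(rng.uniform(40, 100))
            else:
                ck = float(10 ** rng.uniform(1.2, 2.5))
                cd = ck
        abundance[p.name] = (ck, cd)
        fold[p.name] = float(np.log2(cd / ck))

    truth = TruthSet(premirnas=premirnas, mirna_abundance=abundance,
                     fold_changes=fold, ncrna_fraction=ncrna_fraction,
                     seed=seed, dispersion=dispersion,
                     isomir_fraction=isomir_fraction,
                     bad_read_fraction=bad_read_fraction)
    truth.validate()
    return truth


def gen_ncrna_references(rng):
    """Two ncRNA reference sets (GenBank-tagged and Rfam-tagged) covering
    rRNA, tRNA, snRNA and snoRNA, as random decoy sequences."""
    from .annotation import ReferenceSet

    def build(source: str, spec):
        records, types = {}, {}
        for rna_type, n, ln in spec:
            for i in range(n):
                rid = f"{source.lower()}_{rna_type}_{i + 1}"
                records[rid] = _random_seq(rng, ln)
                types[rid] = rna_type
        return ReferenceSet(name=f"{source}_ncRNA", source=source,
                            records=records, types=types)

    genbank = build("GenBank", [("rRNA", 2, 1500), ("rRNA", 1, 600),
                                ("tRNA", 3, 75), ("snRNA", 2, 160),
                                ("snoRNA", 2, 110)])
    rfam = build("Rfam", [("rRNA", 1, 1200), ("tRNA", 2, 75),
                          ("snRNA", 1, 150), ("snoRNA", 1, 100)])
    return genbank, rfam


def gen_mature_reference(truth: TruthSet, rng, n_decoys: int = 30,
                         n_variant: int = 3) -> dict[str, str]:
    """Known-mature miRNA reference: planted conserved matures (a few
    stored as 1-2 nt middle variants, emulating cross-species divergence
    within the 2-mismatch matching bound) plus random decoys."""
    ref: dict[str, str] = {}
    conserved = [p for p in truth.premirnas if p.conserved]
    for idx, p in enumerate(conserved):
        seq = p.mature
        if idx < n_variant:
            s = list(seq)
            n_sub = 1 + idx % 2
            positions = rng.choice(np.arange(4, len(s) - 4), size=n_sub,
                                   replace=False)
            for pos in positions:
                s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
            seq = "".join(s)
        ref[p.known_name] = seq
    for i in range(n_decoys):
        ref[f"kno-decoy{i + 1:03d}"] = _random_seq(rng, 21)
    return ref


@dataclass
class SimulatedData:
    """Everything one simulation produced, in memory plus on disk."""

    truth: TruthSet
    lib_ck: SyntheticLibrary
    lib_cd: SyntheticLibrary
    counts: pd.DataFrame
    transcriptome: dict[str, str]
    mature_ref: dict[str, str]
    ncrna_refs: tuple
    embedded: pd.DataFrame
    target_sites: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


def default_target_specs(truth: TruthSet) -> list[TargetSpec]:
    """Plant perfect, single-wobble and single-mismatch sites for a
    representative subset of the planted miRNAs."""
    specs = []
    names = [p.name for p in truth.premirnas]
    by_name = {p.name: p for p in truth.premirnas}
    picked = 0
    for name in names:
        mature = by_name[name].mature
        if picked % 3 == 0:
            specs.append(TargetSpec(name, 1, []))
        elif picked % 3 == 1:
            pos = next((i + 1 for i, b in enumerate(mature)
                        if i + 1 > 13 and b in "GT"), None)
            specs.append(TargetSpec(name, 1, [(pos, "gu")] if pos else []))
        else:
            specs.append(TargetSpec(name, 1, [(16, "mm")]))
        picked += 1
        if picked >= 9:
            break
    return specs


def simulate(seed: int, outdir, depth: int = 50_000,
             n_background: int = 40, truth: TruthSet | None = None,
             target_specs: list[TargetSpec] | None = None,
             adapter3: str = DEFAULT_ADAPTER3) -> SimulatedData:
    """Generate a full input bundle and write it under `outdir`:
    FASTQ libraries, reference FASTAs and TSV truth side-cars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth is None:
        truth = make_truth_set(seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    genbank, rfam = gen_ncrna_references(rng)
    mature_ref = gen_mature_reference(truth, rng)
    if target_specs is None:
        target_specs = default_target_specs(truth)
    transcriptome, embedded, sites = gen_transcriptome(
        n_background, truth.premirnas, target_specs, rng)
    lib_ck, lib_cd, counts = gen_libraries(
        truth, depth, adapter3=adapter3, rng=rng,
        ncrna_refs=(genbank, rfam))

    paths: dict[str, Path] = {}

    def save_fasta(key, records):
        paths[key] = outdir / f"{key}.fa"
        write_fasta(paths[key], records.items())

    save_fasta("transcriptome", transcriptome)
    save_fasta("mature_ref", mature_ref)
    save_fasta("ncrna_genbank", genbank.records)
    save_fasta("ncrna_rfam", rfam.records)
    for key, refset in (("ncrna_genbank", genbank), ("ncrna_rfam", rfam)):
        tpath = outdir / f"{key}.types.tsv"
        pd.DataFrame(sorted(refset.types.items()),
                     columns=["id", "type"]).to_csv(tpath, sep="\t",
                                                    index=False)
        paths[f"{key}_types"] = tpath
    for lib in (lib_ck, lib_cd):
        key = f"reads_{lib.condition_label.lower()}"
        paths[key] = outdir / f"{key}.fastq"
        write_fastq(paths[key],
                    ((f"{lib.condition_label}_{i:07d}", seq, qual)
                     for i, (seq, qual) in enumerate(lib.reads)))

    pre_df = pd.DataFrame(
        [{"name": p.name, "sequence": p.sequence,
          "mature_start": p.mature_start, "mature_end": p.mature_end,
          "arm": p.arm, "class": "conserved" if p.conserved else "novel",
          "known_name": p.known_name or ""} for p in truth.premirnas])
    ab_df = pd.DataFrame(
        [{"mirna": n, "mean_ck": ck, "mean_cd": cd,
          "true_log2fc": truth.fold_changes[n]}
         for n, (ck, cd) in truth.mirna_abundance.items()])
    for key, df in (("truth_premirnas", pre_df), ("truth_abundance", ab_df),
                    ("truth_counts", counts), ("truth_embedded", embedded),
                    ("truth_target_sites", sites)):
        paths[key] = outdir / f"{key}.tsv"
        df.to_csv(paths[key], sep="\t", index=False, float_format="%.6g")

    return SimulatedData(truth=truth, lib_ck=lib_ck, lib_cd=lib_cd,
                         counts=counts, transcriptome=transcriptome,
                         mature_ref=mature_ref, ncrna_refs=(genbank, rfam),
                         embedded=embedded, target_sites=sites, paths=paths)
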