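"""End-to-end orchestration: clean -> annotate -> discover -> targets ->
differential expression, with a YAML config, full threshold echo, and
TSV/FASTA report files.

All output coordinates are 0-based half-open. Re-running with an
identical config and seed is byte-identical: no timestamps enter the
outputs, every table has a fixed column order and row sort, and floats
are formatted with a fixed format string.
"""

from __future__ import annotations

import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann
from . import diffexp as de
from . import discovery as disc
from . import preprocess as prep
from .io import ensure_exists, read_fasta, read_fastq, revcomp, to_rna, \
    write_tagcount_fasta
from .synthetic import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5
from .targets import ScoringParams, scan_targets

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    reads_ck: str = ""
    reads_cd: str = ""
    transcriptome: str = ""
    mature_ref: str = ""
    ncrna_genbank: str = ""
    ncrna_genbank_types: str = ""
    ncrna_rfam: str = ""
    ncrna_rfam_types: str = ""
    other_ref: str = ""
    outdir: str = "typhamir_out"
    seed: int = 0
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    conserved_max_mismatch: int = 2
    novel: dict = field(default_factory=lambda: asdict(disc.NovelParams()))
    scoring: dict = field(default_factory=lambda: asdict(ScoringParams()))
    p_cut: float = 0.05
    fc_cut: float = 1.5
    tpm_floor: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("novel", "scoring"):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        ensure_exists(self.reads_ck, "CK reads FASTQ")
        ensure_exists(self.reads_cd, "Cd reads FASTQ")
        ensure_exists(self.transcriptome, "transcriptome FASTA")
        ensure_exists(self.mature_ref, "mature miRNA reference FASTA")


@dataclass
class PipelineReport:
    config: PipelineConfig
    stats_ck: prep.CleanStats
    stats_cd: prep.CleanStats
    tags: list
    composition: pd.DataFrame
    conserved: list
    novel: list
    isomirs: list
    target_sites: list
    diffexp: list
    summary: pd.DataFrame
    outdir: Path


def _load_refset(fasta_path, types_path, name, source) -> ann.ReferenceSet:
    records = read_fasta(fasta_path)
    types_df = pd.read_csv(types_path, sep="\t")
    types = dict(zip(types_df["id"], types_df["type"]))
    missing = set(records) - set(types)
    if missing:
        raise ValueError(f"{name}: records without declared type: "
                         f"{sorted(missing)[:3]}")
    return ann.ReferenceSet(name=name, source=source, records=records,
                            types=types)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute all stages and write the report bundle to config.outdir.

    Raises on missing/ill-formed inputs or any violated invariant;
    partially written outputs are removed on failure.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise


def _run(config: PipelineConfig, outdir: Path,
         written: list[Path]) -> PipelineReport:
    log_lines: list[str] = ["typhamir pipeline run", "config:"]
    log_lines += [f"  {line}" for line in
                  yaml.safe_dump(asdict(config), sort_keys=True
                                 ).strip().splitlines()]

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    # ---- preprocess -----------------------------------------------------
    reads_ck = read_fastq(config.reads_ck)
    reads_cd = read_fastq(config.reads_cd)
    inserts_ck, stats_ck = prep.clean_library(reads_ck, config.adapter3,
                                              config.adapter5)
    inserts_cd, stats_cd = prep.clean_library(reads_cd, config.adapter3,
                                              config.adapter5)
    tags = prep.collapse_tags(inserts_ck, inserts_cd)
    if sum(t.count_ck for t in tags) != len(inserts_ck) or \
            sum(t.count_cd for t in tags) != len(inserts_cd):
        raise AssertionError("tag collapse lost reads")
    stats_df = pd.concat([stats_ck.as_frame().assign(library="CK"),
                          stats_cd.as_frame().assign(library="Cd")])
    _write(stats_df, out("clean_stats.tsv"))
    _write(pd.DataFrame([{"sequence": t.sequence, "count_ck": t.count_ck,
                          "count_cd": t.count_cd} for t in tags]),
           out("tags.tsv"))
    write_tagcount_fasta(out("tagcount_ck.fa"), tags, "ck")
    write_tagcount_fasta(out("tagcount_cd.fa"), tags, "cd")
    _write(prep.length_distribution(tags, "total"),
           out("length_distribution_total.tsv"))
    _write(prep.length_distribution(tags, "unique"),
           out("length_distribution_unique.tsv"))
    _write(prep.first_base_bias(tags), out("first_base_bias.tsv"))

    # ---- annotation -----------------------------------------------------
    ncrna_refs = []
    if config.ncrna_genbank:
        ncrna_refs.append(_load_refset(config.ncrna_genbank,
                                       config.ncrna_genbank_types,
                                       "GenBank_ncRNA", "GenBank"))
    if config.ncrna_rfam:
        ncrna_refs.append(_load_refset(config.ncrna_rfam,
                                       config.ncrna_rfam_types,
                                       "Rfam_ncRNA", "Rfam"))
    mature_ref = read_fasta(config.mature_ref)
    other_ref = read_fasta(config.other_ref) if config.other_ref else None
    annotations = ann.annotate_tags(tags, ncrna_refs, mature_ref, other_ref)
    composition = ann.summarize_composition(annotations, tags)
    _write(composition, out("composition.tsv"))

    # ---- miRNA discovery ------------------------------------------------
    transcriptome = read_fasta(config.transcriptome)
    ncrna_cats = set(ann.NCRNA_TYPES)
    non_ncrna = [t for t in tags
                 if annotations.category[t.sequence] not in ncrna_cats]
    tags_by_seq = {t.sequence: t for t in tags}
    hits = disc.match_conserved(non_ncrna, mature_ref,
                                config.conserved_max_mismatch)
    groups: dict[str, list[str]] = {}
    for seq, (ref_name, _mm) in sorted(hits.items()):
        groups.setdefault(ref_name, []).append(seq)
    conserved = disc.cluster_and_quantify(groups, tags_by_seq, "conserved")
    novel_params = disc.NovelParams(**config.novel)
    for rec in conserved:
        rec.precursor = disc.find_precursor(rec.representative_seq,
                                            transcriptome, novel_params)

    exclude = set(hits) | {t.sequence for t in tags
                           if annotations.category[t.sequence]
                           in ncrna_cats or
                           annotations.category[t.sequence] ==
                           "known_miRNA"}
    _cands, novel = disc.predict_novel(non_ncrna, transcriptome,
                                       novel_params, exclude=exclude)
    # a "novel" locus that coincides with a conserved miRNA's precursor
    # (seeded by a long isomiR or by the star strand) is not a new miRNA:
    # keep classes disjoint and report the opposite arm via the pair flag
    hit_seqs = set(hits)

    def on_conserved_locus(rec) -> bool:
        if set(rec.cluster_members) & hit_seqs:
            return True
        c = rec.precursor
        for cons in conserved:
            p = cons.precursor
            if p is not None and p.source_unigene == c.source_unigene \
                    and c.span[0] < p.span[1] and p.span[0] < c.span[1]:
                return True
        return False

    novel = [r for r in novel if not on_conserved_locus(r)]
    for i, rec in enumerate(novel):
        rec.name = f"novel_mir_{i + 1}"
    records = conserved + novel
    isomirs = []
    for rec in records:
        if rec.precursor is not None:
            rec.star_seq = disc.detect_star(rec.precursor, tags)
            isomirs.extend(disc.enumerate_isomirs(rec, tags))

    _write(pd.DataFrame([_record_row(r) for r in records]),
           out("mirna_records.tsv"))
    with open(out("precursors.fa"), "w") as fh:
        for rec in records:
            if rec.precursor is not None:
                c = rec.precursor
                fh.write(f">{rec.name} {c.source_unigene}:"
                         f"{c.span[0]}-{c.span[1]}({c.strand}) "
                         f"mfe={c.mfe:.2f} mfei={c.mfei:.3f}\n"
                         f"{to_rna(c.sequence)}\n{c.fold.dotbracket}\n")
    _write(pd.DataFrame([{
        "parent": i.parent, "sequence": to_rna(i.sequence),
        "offset_5p": i.offset_5p, "offset_3p": i.offset_3p,
        "count_ck": i.count_ck, "count_cd": i.count_cd,
        "canonical": int(i.is_canonical)} for i in isomirs]),
        out("isomirs.tsv"))

    # ---- targets --------------------------------------------------------
    scoring = ScoringParams(**config.scoring)
    target_sites = []
    for rec in records:
        target_sites.extend(
            scan_targets(rec.name, rec.representative_seq, transcriptome,
                         scoring))
    _write(pd.DataFrame([{
        "mirna": s.mirna, "unigene": s.unigene, "start": s.span[0],
        "end": s.span[1], "expectation": s.expectation,
        "duplex_mfe": s.duplex_mfe,
        "alignment": s.alignment.replace("\n", " / ")}
        for s in target_sites]), out("targets.tsv"))

    # ---- differential expression ---------------------------------------
    total_ck = sum(r.expr_ck for r in records)
    total_cd = sum(r.expr_cd for r in records)
    results = de.call_de(records, (max(total_ck, 1), max(total_cd, 1)),
                         config.p_cut, config.fc_cut, config.tpm_floor)
    _write(de.as_frame(results), out("diffexp.tsv"))

    # ---- summary --------------------------------------------------------
    summary = summarize_run(stats_ck, stats_cd, tags, composition,
                            conserved, novel, results)
    _write(summary, out("summary.tsv"))
    log_lines.append(f"records: {len(records)} "
                     f"(conserved {len(conserved)}, novel {len(novel)})")
    log_lines.append(f"target sites: {len(target_sites)}")
    with open(out("run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    with open(out("config_echo.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    return PipelineReport(config=config, stats_ck=stats_ck,
                          stats_cd=stats_cd, tags=tags,
                          composition=composition, conserved=conserved,
                          novel=novel, isomirs=isomirs,
                          target_sites=target_sites, diffexp=results,
                          summary=summary, outdir=outdir)


def _record_row(rec) -> dict:
    c = rec.precursor
    return {
        "name": rec.name, "class": rec.mirna_class,
        "representative": to_rna(rec.representative_seq),
        "n_members": len(rec.cluster_members),
        "expr_ck": rec.expr_ck, "expr_cd": rec.expr_cd,
        "precursor_unigene": c.source_unigene if c else "",
        "precursor_start": c.span[0] if c else -1,
        "precursor_end": c.span[1] if c else -1,
        "precursor_mfe": c.mfe if c else 0.0,
        "precursor_mfei": c.mfei if c else 0.0,
        "arm": c.arm if c else "",
        "star_seq": to_rna(rec.star_seq) if rec.star_seq else "",
    }


def summarize_run(stats_ck, stats_cd, tags, composition, conserved, novel,
                  results) -> pd.DataFrame:
    """One row per headline metric: library stats, shared/specific tags,
    category shares, miRNA counts by class, DE calls."""
    shared_u = sum(1 for t in tags if t.count_ck > 0 and t.count_cd > 0)
    ck_u = sum(1 for t in tags if t.count_ck > 0 and t.count_cd == 0)
    cd_u = sum(1 for t in tags if t.count_ck == 0 and t.count_cd > 0)
    shared_t = sum(t.total for t in tags
                   if t.count_ck > 0 and t.count_cd > 0)
    ck_t = sum(t.total for t in tags if t.count_cd == 0)
    cd_t = sum(t.total for t in tags if t.count_ck == 0)
    n_sig = sum(1 for r in results if r.sig_label)
    rows = [
        ("raw_reads_ck", stats_ck.raw_reads),
        ("raw_reads_cd", stats_cd.raw_reads),
        ("clean_reads_ck", stats_ck.clean_reads),
        ("clean_reads_cd", stats_cd.clean_reads),
        ("unique_tags", len(tags)),
        ("shared_unique_tags", shared_u),
        ("ck_specific_unique_tags", ck_u),
        ("cd_specific_unique_tags", cd_u),
        ("shared_total_reads", shared_t),
        ("ck_specific_total_reads", ck_t),
        ("cd_specific_total_reads", cd_t),
        ("conserved_mirnas", len(conserved)),
        ("novel_mirnas", len(novel)),
        ("mirnas_with_precursor",
         sum(1 for r in conserved + novel if r.precursor is not None)),
        ("mirna_5p3p_pairs",
         sum(1 for r in conserved + novel if r.star_seq)),
        ("significant_mirnas", n_sig),
        ("cd_only_mirnas",
         sum(1 for r in results if r.specific == "Cd_only")),
        ("ck_only_mirnas",
         sum(1 for r in results if r.specific == "CK_only")),
    ]
    for _, row in composition.iterrows():
        rows.append((f"category_{row['category']}_total",
                     int(row["total_ck"] + row["total_cd"])))
    return pd.DataFrame(rows, columns=["metric", "value"])
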