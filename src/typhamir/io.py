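"""FASTA/FASTQ reading and writing helpers (Biopython-backed) plus small
sequence utilities shared across the pipeline.

Sequences are DNA-alphabet (T) internally; `to_rna` renders U for display
in reports, matching the conventional RNA notation of miRNA tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase DNA sequence}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = to_dna(str(rec.seq))
    return out


def write_fasta(path, records: Iterable[tuple[str, str]],
                descriptions: dict[str, str] | None = None) -> None:
    recs = []
    for name, seq in records:
        desc = (descriptions or {}).get(name, "")
        recs.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """FASTQ file -> list of (sequence, quality string), Sanger Phred+33."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append((to_dna(str(rec.seq)),
                    "".join(chr(q + 33) for q in quals)))
    return out


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_tagcount_fasta(path, tags, library: str) -> None:
    """Collapsed tags as read-count FASTA (`>tag{i}_x{count}`) for one
    library; tags with zero count in that library are skipped."""
    attr = f"count_{library.lower()}"
    with open(path, "w") as fh:
        i = 0
        for tag in tags:
            count = getattr(tag, attr)
            if count > 0:
                i += 1
                fh.write(f">tag{i}_x{count}\n{tag.sequence}\n")


def ensure_exists(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p
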