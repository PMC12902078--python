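"""File I/O: FASTA/FASTQ via Biopython, exon-interval tables, YAML config."""

from __future__ import annotations

import os
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .core import ReferenceAnnotation, SeqRecord


def read_fasta(path, evidence_source: str = "SIM", sample_id: str = "") -> list[SeqRecord]:
    return [
        SeqRecord(id=rec.id, nucleotides=str(rec.seq).upper(),
                  sample_id=sample_id, evidence_source=evidence_source)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[SeqRecord], path) -> None:
    bio = [_BioRecord(Seq(r.nucleotides), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path, sample_id: str = "", evidence_source: str = "MPS") -> list[SeqRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(SeqRecord(
            id=rec.id, nucleotides=str(rec.seq).upper(), sample_id=sample_id,
            qualities=list(rec.letter_annotations["phred_quality"]),
            evidence_source=evidence_source))
    return out


def write_fastq(records: list[SeqRecord], path) -> None:
    bio = []
    for r in records:
        b = _BioRecord(Seq(r.nucleotides), id=r.id, description="")
        b.letter_annotations["phred_quality"] = (
            r.qualities if r.qualities is not None else [40] * len(r.nucleotides))
        bio.append(b)
    SeqIO.write(bio, str(path), "fastq")


def read_exon_table(path) -> dict[str, ReferenceAnnotation]:
    """4-column TSV (locus, reference_id, start, end), one row per exon."""
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("locus\t"):
                continue
            locus, ref_id, start, end = line.split("\t")[:4]
            d = rows.setdefault(locus, {"reference_id": ref_id, "exons": []})
            d["exons"].append((int(start), int(end)))
    return {
        locus: ReferenceAnnotation(locus=locus, reference_id=d["reference_id"],
                                   exon_intervals=d["exons"])
        for locus, d in rows.items()
    }


def write_exon_table(annots: dict[str, ReferenceAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\treference_id\tstart\tend\n")
        for locus in sorted(annots):
            a = annots[locus]
            for s, e in a.exon_intervals:
                fh.write(f"{locus}\t{a.reference_id}\t{s}\t{e}\n")


def read_gff3_exons(path, locus: str | None = None) -> dict[str, ReferenceAnnotation]:
    """Minimal GFF3 reader accepting only ``exon`` features (column 3)."""
    rows: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] != "exon":
                continue
            rows.setdefault(parts[0], []).append((int(parts[3]), int(parts[4])))
    return {
        seqid: ReferenceAnnotation(locus=locus or seqid, reference_id=seqid,
                                   exon_intervals=sorted(exons))
        for seqid, exons in rows.items()
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
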