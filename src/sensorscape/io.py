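"""Readers and writers for the pipeline's plain-text interchange formats.

Formats are deliberately boring: tab-separated tables for annotations and
metadata, FASTA for sequences, JSON for ground truth and manifests.  All writers
sort deterministically so identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .extract import AnnotationError, DomainHit, GeneRecord, SensorDomain

ANNOTATION_COLUMNS = [
    "metagenome_id",
    "gene_id",
    "pfam_acc",
    "ali_start",
    "ali_end",
    "gene_copy_number",
    "protein_length",
]


def write_annotations(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene/domain annotations as one TSV row per domain hit.

    A gene with no hits still gets one row with an empty ``pfam_acc`` so that
    per-metagenome gene totals can be recovered from the table alone.
    """
    rows = []
    for g in genes:
        if not g.domain_hits:
            rows.append((g.metagenome_id, g.gene_id, "", 0, 0, g.copy_number, g.protein_length))
        for h in g.domain_hits:
            rows.append(
                (g.metagenome_id, g.gene_id, h.pfam_acc, h.start, h.end, g.copy_number, g.protein_length)
            )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> list[GeneRecord]:
    """Parse an annotation TSV back into :class:`GeneRecord` objects.

    Rows are grouped by (metagenome_id, gene_id) preserving file order; the
    copy number and protein length must agree across a gene's rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"metagenome_id": str, "gene_id": str, "pfam_acc": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    genes: dict[tuple[str, str], GeneRecord] = {}
    for row in df.itertuples(index=False):
        key = (row.metagenome_id, row.gene_id)
        rec = genes.get(key)
        if rec is None:
            rec = GeneRecord(
                metagenome_id=row.metagenome_id,
                gene_id=row.gene_id,
                protein_length=int(row.protein_length),
                copy_number=float(row.gene_copy_number),
            )
            genes[key] = rec
        acc = row.pfam_acc
        if isinstance(acc, str) and acc:
            rec.domain_hits.append(DomainHit(acc, int(row.ali_start), int(row.ali_end)))
    return list(genes.values())


def write_fasta(sequences: Mapping[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_sensor_fasta(domains: Iterable[SensorDomain], path: str | Path) -> None:
    """Sensor-domain FASTA with ``gene_id|domain_index|pfam_acc`` headers."""
    write_fasta([(d.domain_id, d.sequence) for d in domains], path)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"metagenome_id": str})
    if "metagenome_id" not in meta.columns:
        raise AnnotationError(f"{path}: metadata lacks a metagenome_id column")
    return meta


def read_domtblout(path: str | Path) -> list[GeneRecord]:
    """Parse HMMER3 ``--domtblout`` output into gene records.

    Envelope coordinates (columns 20-21) are used as the domain span; the
    target name doubles as the gene id and the metagenome id is left blank for
    the caller to fill in.  Copy numbers are not part of domtblout and default
    to 1.
    """
    genes: dict[str, GeneRecord] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 22:
                raise AnnotationError(f"{path}: short domtblout line: {line.strip()[:60]}")
            gene_id, tlen = parts[0], int(parts[2])
            acc = parts[4].split(".")[0] if parts[4] != "-" else parts[3]
            env_from, env_to = int(parts[19]), int(parts[20])
            rec = genes.setdefault(
                gene_id, GeneRecord(metagenome_id="", gene_id=gene_id, protein_length=tlen)
            )
            rec.domain_hits.append(DomainHit(acc, env_from, env_to))
    return list(genes.values())
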