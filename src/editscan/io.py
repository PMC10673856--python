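"""File IO: FASTA/FASTQ via Biopython, tables via pandas, reports as JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .selection import NCRPeptideRecord, ZONE_LABELS
from .tide import ChromatogramTrace


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise InputError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write reads with a fixed Phred+33 quality."""
    records = []
    for name, seq in reads:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "has_signal_peptide"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"annotation table missing columns: {sorted(missing)}")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "total_reads"} - set(df.columns)
    if missing:
        raise InputError(f"expression table missing columns: {sorted(missing)}")
    return df


write_expression = write_annotation
write_table = write_annotation


def read_trace(path) -> ChromatogramTrace:
    return ChromatogramTrace.from_frame(pd.read_csv(path, sep="\t"))


def write_trace(trace: ChromatogramTrace, path) -> None:
    trace.to_frame().to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def load_peptide_records(
    peptides_fasta, annotation_tsv, expression_tsv=None
) -> list[NCRPeptideRecord]:
    """Assemble NCRPeptideRecords from a peptide FASTA, an annotation table
    (gene_id, has_signal_peptide, signal_cleavage_site) and optionally an
    expression table (gene_id, zone columns, total_reads)."""
    peptides = read_fasta(peptides_fasta)
    annot = read_annotation(annotation_tsv).set_index("gene_id")
    expr = read_expression(expression_tsv).set_index("gene_id") if expression_tsv else None
    records = []
    for gene_id, seq in peptides.items():
        if gene_id not in annot.index:
            raise InputError(f"no annotation row for gene {gene_id!r}")
        row = annot.loc[gene_id]
        has_sp = bool(row["has_signal_peptide"])
        cleavage = row.get("signal_cleavage_site")
        cleavage = int(cleavage) if has_sp and pd.notna(cleavage) else None
        total = None
        zones = None
        if expr is not None:
            if gene_id not in expr.index:
                raise InputError(f"no expression row for gene {gene_id!r}")
            erow = expr.loc[gene_id]
            total = int(erow["total_reads"])
            if set(ZONE_LABELS) <= set(expr.columns):
                zones = {z: int(erow[z]) for z in ZONE_LABELS}
        records.append(NCRPeptideRecord(
            gene_id=gene_id, full_peptide=seq, has_signal_peptide=has_sp,
            signal_cleavage_site=cleavage, total_reads=total, zone_reads=zones,
        ).with_mature())
    return records
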