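"""File-format helpers: FASTA/FASTQ via Biopython, YAML configs, CSV tables."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml
from Bio import SeqIO

from .models import AmpliconConfig, ConditionsTable, GeneModel, LibraryTable, SgRNA, ValidationError


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_reads(path: str | Path) -> Iterator[str]:
    """Yield read sequences from FASTQ(.gz), FASTA, or one-read-per-line text."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    with _open_text(path) as fh:
        if suffix in (".fastq", ".fq"):
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq).upper()
        elif suffix in (".fasta", ".fa", ".fna"):
            for rec in SeqIO.parse(fh, "fasta"):
                yield str(rec.seq).upper()
        else:
            for line in fh:
                line = line.strip()
                if line:
                    yield line.upper()


def write_fastq(reads: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")


def read_gene_model(fasta_path: str | Path, model_path: str | Path) -> GeneModel:
    """Gene model from a single-record FASTA plus a YAML intervals file.

    The YAML carries ``name``, ``cds_intervals`` (list of [start, end),
    0-based) and optional ``intron_margin``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected one FASTA record, got {len(records)}")
    with open(model_path) as fh:
        meta = yaml.safe_load(fh)
    return GeneModel(
        name=meta.get("name", records[0].id),
        sequence=str(records[0].seq).upper(),
        cds_intervals=tuple(tuple(iv) for iv in meta["cds_intervals"]),
        intron_margin=int(meta.get("intron_margin", 10)),
    )


def read_amplicon_config(path: str | Path) -> AmpliconConfig:
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    return AmpliconConfig(
        name=meta["name"],
        anchor=meta["anchor"].upper(),
        reference_window=meta["reference_window"].upper(),
        cut_offset=int(meta["cut_offset"]),
        frame_offset=int(meta.get("frame_offset", 0)),
    )


def read_conditions(path: str | Path) -> ConditionsTable:
    """Conditions CSV with columns (barcode, sample)."""
    df = pd.read_csv(path, dtype=str)
    if not {"barcode", "sample"} <= set(df.columns):
        raise ValidationError("conditions CSV needs 'barcode' and 'sample' columns")
    return ConditionsTable(entries=dict(zip(df["barcode"].str.upper(), df["sample"])))


def write_library(library: LibraryTable, path: str | Path) -> None:
    library.to_frame().to_csv(path, index=False)


def read_library(path: str | Path) -> LibraryTable:
    df = pd.read_csv(path)
    members = []
    for _, row in df.iterrows():
        if bool(row["is_control"]):
            members.append(SgRNA(spacer=row["spacer"], is_control=True))
        else:
            gene = str(row["gene"]) if "gene" in row and pd.notna(row["gene"]) else None
            aa = row.get("target_aa")
            members.append(
                SgRNA(
                    spacer=row["spacer"],
                    pam=row["pam"],
                    strand=row["strand"],
                    cut_pos=int(row["cut_pos"]),
                    target_codon=int(row["target_codon"]) or None,
                    target_aa=str(aa) if pd.notna(aa) and aa else None,
                    gene=gene or None,
                )
            )
    return LibraryTable(members=members)
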