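"""Readers and writers for the standard formats the pipeline consumes.

Coordinate conventions: all in-memory intervals are 0-based half-open.
GFF3 is written/read as 1-based inclusive, BED as 0-based half-open,
per those standards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised for malformed records; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# FASTA / FASTQ (thin wrappers over Biopython)

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class FastqRead:
    name: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise FormatError(f"read {self.name}: sequence/quality length mismatch")


def read_fastq(path: str | Path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# GFF3 / BED

GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table (0-based half-open `start`,`end`) as GFF3.

    Expected columns: contig, start, end, strand, gene_id; optional: role,
    type (defaults to `gene`).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in features.iterrows():
            attrs = [f"ID={row['gene_id']}"]
            if "role" in row and pd.notna(row["role"]):
                attrs.append(f"role={row['role']}")
            fh.write(
                "\t".join([
                    str(row["contig"]),
                    "ragath",
                    str(row.get("type", "gene")),
                    str(int(row["start"]) + 1),  # 1-based inclusive
                    str(int(row["end"])),
                    ".",
                    str(row["strand"]),
                    ".",
                    ";".join(attrs),
                ])
                + "\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into a table with 0-based half-open coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"expected 9 GFF3 columns, got {len(parts)}", lineno)
            try:
                start = int(parts[3]) - 1
                end = int(parts[4])
            except ValueError as exc:
                raise FormatError(f"non-integer coordinate: {exc}", lineno) from None
            if start < 0 or end <= start:
                raise FormatError(f"invalid interval [{parts[3]}, {parts[4]}]", lineno)
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                dict(
                    contig=parts[0],
                    type=parts[2],
                    start=start,
                    end=end,
                    strand=parts[6],
                    gene_id=attrs.get("ID", f"feature{lineno}"),
                    role=attrs.get("role"),
                )
            )
    return pd.DataFrame(
        rows, columns=["contig", "type", "start", "end", "strand", "gene_id", "role"]
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED6 from a table with 0-based half-open start/end.

    Expected columns: contig, start, end, name; optional score, strand.
    """
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            fh.write(
                "\t".join([
                    str(row["contig"]),
                    str(int(row["start"])),
                    str(int(row["end"])),
                    str(row.get("name", ".")),
                    str(row.get("score", 0)),
                    str(row.get("strand", ".")),
                ])
                + "\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED requires at least 3 columns", lineno)
            row = dict(contig=parts[0], start=int(parts[1]), end=int(parts[2]))
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                row["score"] = float(parts[4])
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stockholm-lite seed alignments (alignment + SS_cons consensus structure)

@dataclass
class SeedAlignment:
    names: list[str]
    rows: list[str]
    structure: str
    name: str = "motif"

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError("alignment rows have unequal lengths")
        if self.rows and len(self.structure) != len(self.rows[0]):
            raise FormatError("SS_cons length differs from alignment length")


def read_stockholm(path: str | Path) -> SeedAlignment:
    aln = AlignIO.read(str(path), "stockholm")
    ss = aln.column_annotations.get("secondary_structure", "." * aln.get_alignment_length())
    return SeedAlignment(
        names=[rec.id for rec in aln],
        rows=[str(rec.seq).upper() for rec in aln],
        structure=ss,
        name=getattr(aln, "annotations", {}).get("name", "motif") if hasattr(aln, "annotations") else "motif",
    )


def write_stockholm(aln: SeedAlignment, path: str | Path) -> None:
    width = max(max(len(n) for n in aln.names), len("#=GC SS_cons")) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, row in zip(aln.names, aln.rows):
            fh.write(f"{name:<{width}}{row}\n")
        fh.write(f"{'#=GC SS_cons':<{width}}{aln.structure}\n")
        fh.write("//\n")


# ---------------------------------------------------------------------------
# TSV / JSON

def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
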