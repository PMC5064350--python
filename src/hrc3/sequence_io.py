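"""Readers/writers for the pipeline's interchange formats and shared coordinate types.

All coordinates are 0-based half-open (BED convention) throughout the package;
1-based inclusive coordinates appear only in report output and are flagged as such.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "GenomicInterval",
    "GeneRecord",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_metadata",
]

_VALID_BASES = frozenset("ACGT")
_AMBIGUITY = frozenset("RYSWKMBDHVN")
_STRANDS = frozenset({"+", "-", "."})

GENE_CLASSES = ("ANTP", "LIM", "POU", "ZF", "PRD", "TALE", "other", "none")


@dataclass(frozen=True)
class NucleotideSequence:
    """An upper-cased DNA sequence over {A,C,G,T} (plus N for masked positions)."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        bad = set(self.bases) - _VALID_BASES - {"N"}
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid characters {sorted(bad)} "
                "(normalize with read_fasta / mask policy first)"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.chrom}:{self.start}-{self.end}: negative start")
        if self.start >= self.end:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: empty or inverted interval"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> float:
        """Distance between two intervals: 0 if they overlap or touch, inf across chromosomes."""
        if self.chrom != other.chrom:
            return float("inf")
        return float(max(0, max(self.start, other.start) - min(self.end, other.end)))


@dataclass
class GeneRecord:
    """A coding gene: CDS sequence plus optional genomic locus and class annotation."""

    gene_id: str
    cds: NucleotideSequence
    class_label: str = "none"
    locus: Optional[GenomicInterval] = None
    paralog_number: Optional[int] = None

    def __post_init__(self) -> None:
        if self.class_label not in GENE_CLASSES:
            raise ValueError(f"gene {self.gene_id!r}: unknown class {self.class_label!r}")
        if self.paralog_number is not None and not (1 <= self.paralog_number <= 13):
            raise ValueError(
                f"gene {self.gene_id!r}: paralog_number {self.paralog_number} outside [1,13]"
            )


def parse_paralog_number(gene_id: str) -> Optional[int]:
    """Trailing integer of a gene id (HOXA10 -> 10), None if absent or out of [1,13]."""
    m = re.search(r"(\d+)$", gene_id)
    if not m:
        return None
    n = int(m.group(1))
    return n if 1 <= n <= 13 else None


def _normalize_bases(raw: str, record_id: str, ambiguity: str) -> str:
    bases = raw.upper().replace("U", "T")
    bad = [(i, b) for i, b in enumerate(bases) if b not in _VALID_BASES]
    if not bad:
        return bases
    if ambiguity == "mask":
        chars = list(bases)
        for i, b in bad:
            if b in _AMBIGUITY:
                chars[i] = "N"
            else:
                raise ValueError(
                    f"record {record_id!r}: non-nucleotide character {b!r} at position {i + 1}"
                )
        return "".join(chars)
    i, b = bad[0]
    raise ValueError(
        f"record {record_id!r}: non-ACGT residue {b!r} at position {i + 1} "
        "(ambiguity policy 'reject'; use ambiguity='mask' to mask as N)"
    )


def read_fasta(path: str | Path, ambiguity: str = "reject") -> list[NucleotideSequence]:
    """Read a FASTA file into NucleotideSequence records, in file order.

    Parameters
    ----------
    ambiguity : {"reject", "mask"}
        "reject" raises on any non-ACGT residue; "mask" converts IUPAC ambiguity
        codes to N (masked downstream).
    """
    if ambiguity not in ("reject", "mask"):
        raise ValueError(f"unknown ambiguity policy {ambiguity!r}")
    records = [
        NucleotideSequence(rec.id, _normalize_bases(str(rec.seq), rec.id, ambiguity))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into 0-based half-open intervals; track/comment lines are skipped."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end} (half-open, empty interval)"
                )
            label = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand == "−":  # unicode minus tolerated on input
                strand = "-"
            intervals.append(GenomicInterval(chrom, start, end, strand=strand, label=label))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6; round-trips through read_bed on chrom/start/end/strand/label."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            chrom, length = fields[0], int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive chromosome length")
            if chrom in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            sizes[chrom] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_gene_metadata(path: str | Path) -> pd.DataFrame:
    """Gene metadata TSV: gene_id, class, chrom, start, end, strand[, paralog_number]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "class", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if "paralog_number" not in df.columns:
        df["paralog_number"] = [parse_paralog_number(g) for g in df["gene_id"]]
    return df


def genes_from_metadata(
    seqs: Iterable[NucleotideSequence], metadata: pd.DataFrame
) -> list[GeneRecord]:
    """Join FASTA records with a metadata table into GeneRecords (inner join on gene_id)."""
    meta = metadata.set_index("gene_id")
    genes = []
    for s in seqs:
        if s.id not in meta.index:
            continue
        row = meta.loc[s.id]
        pn = row.get("paralog_number")
        pn = None if pd.isna(pn) else int(pn)
        genes.append(
            GeneRecord(
                gene_id=s.id,
                cds=s,
                class_label=str(row["class"]),
                locus=GenomicInterval(
                    str(row["chrom"]), int(row["start"]), int(row["end"]), strand=str(row["strand"])
                ),
                paralog_number=pn,
            )
        )
    return genes
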