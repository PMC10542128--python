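"""Genomic data model and GFF3/FASTA/TSV readers and writers.

Coordinates are 1-based inclusive throughout (GFF3 convention).  The
intergenic gap between two genes on the same contig is
``start2 - end1 - 1``: abutting genes have gap 0 and overlapping reading
frames yield negative gaps.  Protein sequences are taken from the
companion FASTA as given; no translation is performed — the pipeline is
annotation-driven.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO


class GFFParseError(ValueError):
    """Raised for a malformed GFF3 line; message names the line number."""


@dataclass
class DomainHit:
    """A domain annotation on a protein (built-in profile scan or imported)."""

    domain_label: str
    start_aa: int
    end_aa: int
    evalue: float
    source: str = "builtin"  # {builtin, external}

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.end_aa < self.start_aa:
            raise ValueError(
                f"invalid domain span {self.start_aa}..{self.end_aa}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")


@dataclass
class GeneFeature:
    """A protein-coding gene with coordinates, strand and annotations."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_length: int
    protein_seq: str | None = None
    annotations: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.protein_seq is not None and self.protein_length != len(self.protein_seq):
            raise ValueError(
                f"{self.gene_id}: protein_length {self.protein_length} != "
                f"len(protein_seq) {len(self.protein_seq)}"
            )

    def has_domain(self, label: str) -> bool:
        return any(h.domain_label == label for h in self.annotations)

    def best_hit(self, labels: Iterable[str]) -> DomainHit | None:
        """Lowest-evalue hit among the given labels, or None."""
        labels = set(labels)
        hits = [h for h in self.annotations if h.domain_label in labels]
        return min(hits, key=lambda h: h.evalue) if hits else None


@dataclass
class GenomeRecord:
    """One contig: ordered, stranded protein-coding genes."""

    contig_id: str
    length: int
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id} on {self.contig_id}")
            seen.add(g.gene_id)
            if g.end > self.length:
                raise ValueError(
                    f"{g.gene_id} end {g.end} exceeds contig length {self.length}"
                )

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def index_of(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return i
        raise KeyError(gene_id)


def intergenic_gap(a: GeneFeature, b: GeneFeature) -> int:
    """Signed intergenic distance in nt between two same-contig genes.

    Arguments are normalized so the upstream-by-start gene comes first;
    the result is ``start2 - end1 - 1`` (0 for abutting genes, negative
    for overlapping reading frames).
    """
    if a.contig_id != b.contig_id:
        raise ValueError(
            f"genes on different contigs: {a.contig_id} vs {b.contig_id}"
        )
    if a.start > b.start:
        a, b = b, a
    return b.start - a.end - 1


# ---------------------------------------------------------------------------
# GFF3 + FASTA reading


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"attribute {item!r} lacks '='")
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_genome(
    gff_path: str | Path,
    fasta_path: str | Path,
    id_attribute: str = "ID",
) -> list[GenomeRecord]:
    """Read CDS features from GFF3 and attach proteins from FASTA.

    Returns one GenomeRecord per contig, genes sorted by start.  CDS IDs
    absent from the FASTA are kept without a sequence and reported via a
    warning; FASTA-only IDs are ignored.
    """
    proteins = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    contigs: dict[str, list[GeneFeature]] = {}
    lengths: dict[str, int] = {}
    missing: list[str] = []

    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(
                    f"{gff_path}, line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(cols)}"
                )
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
                attributes = _parse_attributes(attrs)
            except ValueError as exc:
                raise GFFParseError(f"{gff_path}, line {lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise GFFParseError(
                    f"{gff_path}, line {lineno}: bad strand {strand!r}"
                )
            gene_id = attributes.get(id_attribute)
            if gene_id is None:
                raise GFFParseError(
                    f"{gff_path}, line {lineno}: CDS lacks {id_attribute!r} attribute"
                )
            seq = proteins.get(gene_id)
            if seq is None:
                missing.append(gene_id)
                plen = (end_i - start_i + 1) // 3 - 1
            else:
                plen = len(seq)
            contigs.setdefault(seqid, []).append(
                GeneFeature(
                    gene_id=gene_id,
                    contig_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    protein_length=plen,
                    protein_seq=seq,
                )
            )

    if missing:
        warnings.warn(
            f"{len(missing)} CDS IDs missing from FASTA: {missing[:10]}",
            stacklevel=2,
        )

    records = []
    for contig_id, genes in contigs.items():
        length = lengths.get(contig_id, max(g.end for g in genes))
        records.append(GenomeRecord(contig_id=contig_id, length=length, genes=genes))
    records.sort(key=lambda r: r.contig_id)
    return records


def write_genome(
    records: Sequence[GenomeRecord],
    gff_path: str | Path,
    fasta_path: str | Path,
) -> None:
    """Write GenomeRecords to GFF3 (CDS features) and protein FASTA."""
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for rec in records:
            gff.write(f"##sequence-region {rec.contig_id} 1 {rec.length}\n")
        for rec in records:
            for g in rec.genes:
                gff.write(
                    f"{rec.contig_id}\tcoconut_census\tCDS\t{g.start}\t{g.end}"
                    f"\t.\t{g.strand}\t0\tID={g.gene_id}\n"
                )
    with open(fasta_path, "w") as fa:
        for rec in records:
            for g in rec.genes:
                if g.protein_seq is not None:
                    fa.write(f">{g.gene_id}\n{g.protein_seq}\n")


# ---------------------------------------------------------------------------
# TSV reports


def write_report(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a list of dict rows as a deterministic TSV.

    Column order is the given ``columns`` or the union of keys in first-seen
    order.  Missing/None values serialize as empty cells.  Output is
    byte-identical for identical input.
    """
    if columns is None:
        cols: list[str] = []
        for row in rows:
            for key in row:
                if key not in cols:
                    cols.append(key)
        columns = cols
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            cells = []
            for col in columns:
                val = row.get(col)
                cells.append("" if val is None else str(val))
            fh.write("\t".join(cells) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by write_report (or any headered TSV)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [
            dict(zip(header, line.rstrip("\n").split("\t")))
            for line in fh
            if line.strip()
        ]
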