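"""Readers and writers for the formats the pipeline touches.

All coordinates are stored 0-based half-open internally; GFF/GTF (1-based,
inclusive) is converted at the boundary. Readers reject inconsistent
coordinates rather than repairing them.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence

from Bio import SeqIO

from .core import Genome, ReadAlignment, Region, TssRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_regions_bed",
    "write_regions_bed",
    "read_alignments",
    "write_alignments",
    "read_alignments_sam",
    "read_tss",
    "write_truth_bed",
]

ALIGNMENT_COLUMNS = ("contig", "start", "end", "strand", "source_tag")


def read_fasta(path: str) -> Genome:
    """Load a FASTA file into a Genome; sequences are uppercased."""
    contigs = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in contigs:
            raise ValueError(f"duplicate FASTA header: {record.id!r}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise ValueError(f"no sequences found in {path}")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_regions_bed(path: str) -> List[Region]:
    """Parse a BED3+ file; coordinates kept verbatim (already half-open)."""
    regions: List[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            regions.append(Region(fields[0], start, end, name=name, strand=strand))
    return regions


def write_regions_bed(regions: Iterable[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.name or '.'}\t0\t{r.strand or '.'}\n"
            )


def read_alignments(path: str, genome: Optional[Genome] = None) -> List[ReadAlignment]:
    """Read the alignment TSV dialect: contig, start, end, strand[, source_tag].

    A header line starting with ``contig`` or ``#`` is skipped. If ``genome``
    is given, spans are validated against contig bounds.
    """
    out: List[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("contig\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            tag = fields[4] if len(fields) > 4 else "shear"
            aln = ReadAlignment(fields[0], start, end, fields[3], tag)
            if genome is not None:
                if aln.contig not in genome:
                    raise ValueError(f"{path}:{lineno}: unknown contig {aln.contig!r}")
                if aln.end > genome.length(aln.contig):
                    raise ValueError(
                        f"{path}:{lineno}: alignment end {aln.end} exceeds contig length"
                    )
            out.append(aln)
    return out


def write_alignments(alignments: Iterable[ReadAlignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_COLUMNS) + "\n")
        for a in alignments:
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.strand}\t{a.source_tag}\n")


def read_alignments_sam(path: str, genome: Optional[Genome] = None) -> List[ReadAlignment]:
    """Ingest mapped records from SAM/BAM behind the same alignment contract.

    Only span and strand are used: the reference span is taken from the
    aligned coordinates and the strand from the reverse flag, so a
    reverse-strand record's 5' terminal is its rightmost reference base.
    """
    import pysam

    out: List[ReadAlignment] = []
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            aln = ReadAlignment(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
            if genome is not None and aln.end > genome.length(aln.contig):
                raise ValueError(
                    f"{path}: alignment end {aln.end} exceeds contig {aln.contig!r}"
                )
            out.append(aln)
    return out


def read_tss(path: str, format: str = "tsv", feature_types: Sequence[str] = ("gene",)) -> List[TssRecord]:
    """Load transcription start sites.

    ``tsv``: three columns contig, 0-based position, strand.
    ``gff``: GFF3/GTF; for each feature of a requested type the TSS is the
    1-based start converted to 0-based on "+", and the feature end minus one
    on "-".
    """
    records: List[TssRecord] = []
    if format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                records.append(TssRecord(fields[0], int(fields[1]), fields[2]))
    elif format == "gff":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 8:
                    raise ValueError(f"{path}:{lineno}: expected >= 8 GFF columns")
                if fields[2] not in feature_types:
                    continue
                start1, end1 = int(fields[3]), int(fields[4])
                if start1 < 1 or end1 < start1:
                    raise ValueError(f"{path}:{lineno}: invalid GFF span")
                strand = fields[6]
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: strandless feature")
                pos = start1 - 1 if strand == "+" else end1 - 1
                records.append(TssRecord(fields[0], pos, strand))
    else:
        raise ValueError(f"unknown TSS format {format!r}")
    return records


def write_truth_bed(truth, path: str, motif_name: str = ".") -> None:
    """Write planted methylation truth as BED6 (score = 1000 x methyl fraction)."""
    rows = sorted(truth.sites.items())
    with open(path, "w") as fh:
        for (contig, pos, strand), frac in rows:
            fh.write(
                f"{contig}\t{pos}\t{pos + 1}\t{motif_name}\t{round(1000 * frac)}\t{strand}\n"
            )
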