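"""Readers/writers and genomic summaries shared by every pipeline stage.

External files use the community conventions (FASTA; GFF3 with 1-based
inclusive coordinates; TSV with a header row).  All internal arithmetic is
0-based half-open; the conversion happens here, at the I/O boundary, and
nowhere else.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("gfam")

CHROMOSOME_RE = re.compile(r"^[1-7][ABD]$|^Un$")


class FastaParseError(ValueError):
    """Raised for malformed or inconsistent FASTA input."""


class GffParseError(ValueError):
    """Raised for structurally invalid gene models."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein (or promoter) sequence with a unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"sequence for {self.id!r} must be uppercase")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """A gene model: chromosome span plus exon intervals.

    Coordinates are 0-based half-open.  ``exon_intervals`` are sorted,
    non-overlapping and contained in ``[start, end)``.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exon_intervals: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = None
        for s, e in self.exon_intervals:
            if s >= e:
                raise GffParseError(f"{self.gene_id}: empty exon interval ({s}, {e})")
            if s < self.start or e > self.end:
                raise GffParseError(
                    f"{self.gene_id}: exon ({s}, {e}) outside locus span "
                    f"({self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise GffParseError(f"{self.gene_id}: exon intervals overlap or are unsorted")
            prev_end = e

    @property
    def sub_genome(self) -> str:
        """Trailing letter of a wheat-style chromosome label, else 'Un'."""
        if CHROMOSOME_RE.match(self.chromosome) and self.chromosome != "Un":
            return self.chromosome[-1]
        return "Un"


@dataclass(frozen=True)
class GeneStructureSummary:
    gene_id: str
    n_exons: int
    n_introns: int
    intronless: bool


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are whitespace-stripped and uppercased; duplicate identifiers
    are an error; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    records = list(records)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )
    logger.info("write_fasta: %d records to %s", len(records), path)


def read_gff3_genes(path: str | Path) -> list[GeneLocus]:
    """Build one :class:`GeneLocus` per mRNA feature from a GFF3 file.

    GFF3 is 1-based inclusive; the returned loci are 0-based half-open.
    Exons lacking a ``Parent`` attribute are skipped with a warning; an exon
    outside its parent's span is an error.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    loci: list[GeneLocus] = []
    for mrna in db.features_of_type("mRNA"):
        exons: list[tuple[int, int]] = []
        for exon in db.children(mrna, featuretype="exon", order_by="start"):
            if "Parent" not in exon.attributes:
                logger.warning("%s: exon at %d-%d has no Parent; skipped", path, exon.start, exon.end)
                continue
            exons.append((exon.start - 1, exon.end))  # to 0-based half-open
        # orphan exons (unlinked by gffutils) cannot reach here; span check below
        for s, e in exons:
            if s < mrna.start - 1 or e > mrna.end:
                raise GffParseError(
                    f"{path}: exon ({s + 1}, {e}) outside mRNA {mrna.id} span "
                    f"({mrna.start}, {mrna.end})"
                )
        loci.append(
            GeneLocus(
                gene_id=mrna.id,
                chromosome=mrna.seqid,
                start=mrna.start - 1,
                end=mrna.end,
                strand=mrna.strand if mrna.strand in "+-" else "+",
                exon_intervals=tuple(sorted(exons)),
            )
        )
    logger.info("read_gff3_genes: %d mRNA loci from %s", len(loci), path)
    return loci


def write_gff3_genes(loci: Iterable[GeneLocus], path: str | Path) -> None:
    """Write loci back to GFF3 (1-based inclusive), one mRNA + exon rows each."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            fh.write(
                f"{locus.chromosome}\tgfam\tmRNA\t{locus.start + 1}\t{locus.end}\t.\t"
                f"{locus.strand}\t.\tID={locus.gene_id}\n"
            )
            for i, (s, e) in enumerate(locus.exon_intervals, 1):
                fh.write(
                    f"{locus.chromosome}\tgfam\texon\t{s + 1}\t{e}\t.\t{locus.strand}\t.\t"
                    f"ID={locus.gene_id}.exon{i};Parent={locus.gene_id}\n"
                )


def gene_structure_summary(locus: GeneLocus) -> GeneStructureSummary:
    """Exon/intron counts for one locus; a single-exon gene is intronless."""
    n_exons = len(locus.exon_intervals)
    if n_exons == 0:
        raise ValueError(f"{locus.gene_id}: locus has no exon intervals")
    n_introns = n_exons - 1
    return GeneStructureSummary(
        gene_id=locus.gene_id,
        n_exons=n_exons,
        n_introns=n_introns,
        intronless=n_introns == 0,
    )


def chromosome_distribution(
    loci: Sequence[GeneLocus],
) -> tuple[dict[str, int], dict[str, int]]:
    """Counts per chromosome and per sub-genome (A/B/D; 'Un' separate).

    Unparseable chromosome labels are tallied under 'Un' with a warning.
    The counts in each map sum to ``len(loci)``.
    """
    per_chrom: Counter[str] = Counter()
    per_subgenome: Counter[str] = Counter()
    for locus in loci:
        label = locus.chromosome
        if not CHROMOSOME_RE.match(label):
            logger.warning("unparseable chromosome label %r counted as 'Un'", label)
            label = "Un"
        per_chrom[label] += 1
        per_subgenome[locus.sub_genome] += 1
    return dict(per_chrom), dict(per_subgenome)


def extract_promoters(
    genome: dict[str, str], loci: Sequence[GeneLocus], length: int = 2000
) -> list[ProteinRecord]:
    """Strand-aware promoter extraction: ``length`` bp upstream of each locus.

    On '+' the window ends at the locus start; on '-' it begins at the locus
    end and is reverse-complemented.  Windows are truncated at chromosome
    boundaries.
    """
    out: list[ProteinRecord] = []
    for locus in loci:
        chrom = genome.get(locus.chromosome)
        if chrom is None:
            logger.warning("%s: chromosome %s absent from genome; skipped", locus.gene_id, locus.chromosome)
            continue
        if locus.strand == "+":
            seq = chrom[max(0, locus.start - length) : locus.start]
        else:
            seq = str(Seq(chrom[locus.end : locus.end + length]).reverse_complement())
        if seq:
            out.append(ProteinRecord(id=locus.gene_id, sequence=seq.upper()))
    return out
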