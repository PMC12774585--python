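"""Genome FASTA / GFF3 parsing into an in-memory locus representation.

Coordinate convention
---------------------
All coordinates inside the package are **0-based, half-open, plus-strand
genomic** positions. Strand is applied only when sequence is extracted
(:func:`extract_region`). GFF3's 1-based inclusive coordinates are converted
once, at parse time, and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "AnnotationError",
    "FormatError",
    "GenomeAssembly",
    "GeneModel",
    "IsoformModel",
    "extract_region",
    "parse_fasta",
    "parse_gff3",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Raised for malformed FASTA input."""


class AnnotationError(ValueError):
    """Raised for GFF3 gene models that violate coding-sequence invariants."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeAssembly:
    """Immutable map of contig name -> uppercase DNA sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"record {name!r} contains non-nucleotide characters: "
                    f"{sorted(bad)}"
                )
            if not seq:
                raise FormatError(f"record {name!r} is empty")

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        return extract_region(self, contig, start, end, strand)


@dataclass(frozen=True)
class IsoformModel:
    """One transcript isoform: exon and CDS intervals plus codon anchors.

    ``start_codon`` is the genomic position of the first CDS base in
    transcription order (for a minus-strand gene this is the numerically
    largest CDS base). ``stop_codon`` is the genomic position of the first
    base of the stop codon, again in transcription order.
    """

    isoform_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    start_codon: int
    stop_codon: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    contig: str
    strand: str
    isoforms: tuple[IsoformModel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise AnnotationError(f"gene {self.gene_id} has no isoforms")
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id} has bad strand {self.strand!r}")

    def isoform(self, isoform_id: str | None = None) -> IsoformModel:
        """Return the named isoform, or the first (annotation-order) one.

        When no isoform is named the first one is used and a warning is
        emitted, mirroring a pull-down default while nudging users to choose
        deliberately.
        """
        if isoform_id is None:
            if len(self.isoforms) > 1:
                warnings.warn(
                    f"gene {self.gene_id}: no isoform selected, defaulting to "
                    f"{self.isoforms[0].isoform_id} (of {len(self.isoforms)})",
                    stacklevel=2,
                )
            return self.isoforms[0]
        for iso in self.isoforms:
            if iso.isoform_id == isoform_id:
                return iso
        raise KeyError(
            f"gene {self.gene_id} has no isoform {isoform_id!r}; available: "
            f"{[i.isoform_id for i in self.isoforms]}"
        )


def parse_fasta(path: str | Path) -> GenomeAssembly:
    """Read a (multi-record) FASTA file into a :class:`GenomeAssembly`.

    Sequences are uppercased; ``N`` is allowed; empty records and
    non-nucleotide characters are rejected with a :class:`FormatError`
    naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate contig name {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"record {record.id!r} is empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {record.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeAssembly(sequences)


def extract_region(
    assembly: GenomeAssembly, contig: str, start: int, end: int, strand: str = "+"
) -> str:
    """Extract ``[start, end)`` from *contig*; reverse-complemented for '−'."""
    if contig not in assembly.sequences:
        raise KeyError(f"unknown contig {contig!r}")
    seq = assembly.sequences[contig]
    if not (0 <= start <= end <= len(seq)):
        raise IndexError(
            f"interval [{start}, {end}) out of bounds for contig "
            f"{contig!r} of length {len(seq)}"
        )
    sub = seq[start:end]
    if strand in ("-", "−"):
        return revcomp(sub)
    if strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    return sub


def spliced_cds(assembly: GenomeAssembly, contig: str, strand: str,
                cds: tuple[tuple[int, int], ...] | list[tuple[int, int]]) -> str:
    """Concatenate CDS intervals in transcription order, strand-corrected."""
    parts = [extract_region(assembly, contig, s, e, "+") for s, e in cds]
    joined = "".join(parts)
    return revcomp(joined) if strand == "-" else joined


def _validate_isoform(
    iso_id: str,
    contig: str,
    strand: str,
    cds: list[tuple[int, int]],
    assembly: GenomeAssembly,
) -> None:
    if not cds:
        raise AnnotationError(f"isoform {iso_id}: no CDS intervals")
    for (s0, e0), (s1, e1) in zip(cds, cds[1:]):
        if s1 < e0:
            raise AnnotationError(f"isoform {iso_id}: overlapping/unsorted CDS")
    total = sum(e - s for s, e in cds)
    if total % 3 != 0:
        raise AnnotationError(
            f"isoform {iso_id}: CDS length {total} not divisible by 3"
        )
    seq = spliced_cds(assembly, contig, strand, cds)
    if not seq.startswith("ATG"):
        raise AnnotationError(f"isoform {iso_id}: CDS does not start with ATG")
    if seq[-3:] not in STOP_CODONS:
        raise AnnotationError(f"isoform {iso_id}: CDS does not end in a stop codon")
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise AnnotationError(
                f"isoform {iso_id}: internal stop codon at CDS offset {i}"
            )


def parse_gff3(path: str | Path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Parse a GFF3 file with gene/mRNA/CDS features into gene models.

    CDS rows link to mRNAs and mRNAs to genes via ``Parent`` attributes.
    1-based inclusive GFF3 coordinates are converted to the internal
    0-based half-open convention here and only here. Every isoform is
    validated against the assembly (ATG start, stop end, length ≡ 0 mod 3,
    no internal stop); violations raise :class:`AnnotationError` naming the
    isoform.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    # referential integrity first: orphan mRNA/CDS rows
    for mrna in db.features_of_type("mRNA"):
        for parent in mrna.attributes.get("Parent", []):
            if parent not in gene_ids:
                raise AnnotationError(f"mRNA {mrna.id}: unknown Parent {parent!r}")
    mrna_ids = {m.id for m in db.features_of_type("mRNA")}
    for cds_row in db.features_of_type("CDS"):
        for parent in cds_row.attributes.get("Parent", []):
            if parent not in mrna_ids:
                raise AnnotationError(
                    f"CDS {cds_row.id}: unknown Parent {parent!r}"
                )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in assembly.sequences:
            raise AnnotationError(
                f"gene {gene.id}: unknown contig {gene.seqid!r}"
            )
        isoforms: list[IsoformModel] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            for parent in mrna.attributes.get("Parent", []):
                if parent not in gene_ids:
                    raise AnnotationError(
                        f"mRNA {mrna.id}: unknown Parent {parent!r}"
                    )
            exons = sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon")
            )
            cds = sorted(
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="CDS")
            )
            _validate_isoform(mrna.id, gene.seqid, gene.strand, cds, assembly)
            if gene.strand == "+":
                start_codon = cds[0][0]
                stop_codon = cds[-1][1] - 3
            else:
                start_codon = cds[-1][1] - 1
                stop_codon = cds[0][0] + 2
            isoforms.append(
                IsoformModel(
                    isoform_id=mrna.id,
                    exons=tuple(exons) if exons else tuple(cds),
                    cds=tuple(cds),
                    start_codon=start_codon,
                    stop_codon=stop_codon,
                )
            )
        if not isoforms:
            raise AnnotationError(f"gene {gene.id}: no mRNA children")
        symbol = gene.attributes.get("Name", [gene.id])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                symbol=symbol,
                contig=gene.seqid,
                strand=gene.strand,
                isoforms=tuple(isoforms),
            )
        )
    return models
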