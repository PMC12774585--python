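"""Seeded synthetic mini-genome generator.

Produces a random genome FASTA plus a GFF3 annotation with valid gene
models (ATG … stop, spliced CDS a multiple of 3 with no internal stop,
optional introns) and a truth table recording every gene's coordinates and
CDS sequence. Identical specs produce byte-identical output. Optionally
plants an exact duplicate of a guide locus elsewhere in the genome so
off-target counting has a known positive control.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .genome_io import revcomp

__all__ = ["FixtureSpec", "GeneTruth", "MiniGenome", "make_mini_genome"]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    n_contigs: int = 1
    contig_length: int = 60_000
    n_genes: int = 5
    exons_per_gene: int = 2
    cds_codons: int = 300
    intron_length: int = 80
    seed: int = 42
    planted_duplicates: int = 0

    def validate(self) -> None:
        if min(self.n_contigs, self.contig_length, self.n_genes,
               self.exons_per_gene, self.cds_codons) < 1:
            raise FixtureError("all fixture dimensions must be >= 1")
        # each gene needs flanks for ~1 kb arms and 1.2 kb primer windows
        footprint = self.gene_footprint + 2 * self.flank
        if self.n_genes_per_contig * footprint > self.contig_length:
            raise FixtureError(
                f"contig_length {self.contig_length} too short for "
                f"{self.n_genes} genes of footprint {footprint}"
            )

    @property
    def n_genes_per_contig(self) -> int:
        return -(-self.n_genes // self.n_contigs)

    @property
    def gene_footprint(self) -> int:
        return 3 * self.cds_codons + (self.exons_per_gene - 1) * self.intron_length

    @property
    def flank(self) -> int:
        return 2800


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    contig: str
    strand: str
    gene_start: int          # 0-based half-open genomic span
    gene_end: int
    start_codon: int         # genomic position of first CDS base
    stop_codon: int          # genomic position of stop codon's first base
    cds_intervals: tuple[tuple[int, int], ...]
    cds_seq: str             # spliced, transcript orientation


@dataclass(frozen=True)
class MiniGenome:
    fasta: Path
    gff3: Path
    truth: tuple[GeneTruth, ...]
    planted: tuple[dict, ...]


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n-2) random non-stop codons + random stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][int(rng.integers(0, 3))])
    return "".join(codons)


def _random_intron(rng: np.random.Generator, length: int) -> str:
    body = "".join(_BASES[i] for i in rng.integers(0, 4, size=max(length - 4, 0)))
    return "GT" + body + "AG"


def _split_cds(rng: np.random.Generator, cds: str, n_exons: int) -> list[str]:
    """Split a CDS into n_exons pieces; terminal pieces keep >= 6 bases so
    start/stop codons are never broken across introns."""
    if n_exons == 1:
        return [cds]
    n = len(cds)
    while True:
        points = sorted(rng.integers(6, n - 6, size=n_exons - 1).tolist())
        if len(set(points)) == n_exons - 1 and all(
            b - a >= 6 for a, b in zip(points, points[1:])
        ):
            break
    pieces, prev = [], 0
    for p in points + [n]:
        pieces.append(cds[prev:p])
        prev = p
    return pieces


def make_mini_genome(spec: FixtureSpec, out_dir: str | Path) -> MiniGenome:
    """Write ``genome.fa``, ``genes.gff3`` and ``truth.json`` under *out_dir*."""
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    contigs: dict[str, list[str]] = {}
    truths: list[GeneTruth] = []
    gff_rows: list[str] = ["##gff-version 3"]
    gene_no = 0
    for ci in range(spec.n_contigs):
        contig = f"chr{ci + 1}"
        seq = list("".join(
            _BASES[i] for i in rng.integers(0, 4, size=spec.contig_length)
        ))
        genes_here = min(spec.n_genes - gene_no, spec.n_genes_per_contig)
        slot = spec.contig_length // max(genes_here, 1)
        for gi in range(genes_here):
            gene_no += 1
            gene_id = f"g{gene_no}"
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            cds = _random_orf(rng, spec.cds_codons)
            pieces = _split_cds(rng, cds, spec.exons_per_gene)
            introns = [
                _random_intron(rng, spec.intron_length)
                for _ in range(len(pieces) - 1)
            ]
            tx = pieces[0] + "".join(
                i + p for i, p in zip(introns, pieces[1:])
            )
            # place the gene centrally in its slot, leaving flanks
            slot_lo = gi * slot
            lo_min = slot_lo + spec.flank
            lo_max = slot_lo + slot - spec.flank - len(tx)
            if lo_max <= lo_min:
                raise FixtureError("contig too short for requested layout")
            gene_start = int(rng.integers(lo_min, lo_max))
            genomic_tx = tx if strand == "+" else revcomp(tx)
            seq[gene_start : gene_start + len(tx)] = genomic_tx

            # genomic CDS intervals (plus-strand sorted)
            intervals_tx: list[tuple[int, int]] = []
            off = 0
            for k, piece in enumerate(pieces):
                intervals_tx.append((off, off + len(piece)))
                off += len(piece)
                if k < len(introns):
                    off += len(introns[k])
            if strand == "+":
                cds_intervals = sorted(
                    (gene_start + a, gene_start + b) for a, b in intervals_tx
                )
            else:
                L = len(tx)
                cds_intervals = sorted(
                    (gene_start + L - b, gene_start + L - a)
                    for a, b in intervals_tx
                )
            if strand == "+":
                start_codon = cds_intervals[0][0]
                stop_codon = cds_intervals[-1][1] - 3
            else:
                start_codon = cds_intervals[-1][1] - 1
                stop_codon = cds_intervals[0][0] + 2
            gene_end = gene_start + len(tx)
            truths.append(GeneTruth(
                gene_id=gene_id, contig=contig, strand=strand,
                gene_start=gene_start, gene_end=gene_end,
                start_codon=start_codon, stop_codon=stop_codon,
                cds_intervals=tuple(cds_intervals), cds_seq=cds,
            ))
            mrna_id = f"{gene_id}.t1"
            gff_rows.append("\t".join([
                contig, "fixture", "gene", str(gene_start + 1), str(gene_end),
                ".", strand, ".", f"ID={gene_id};Name={gene_id}",
            ]))
            gff_rows.append("\t".join([
                contig, "fixture", "mRNA", str(gene_start + 1), str(gene_end),
                ".", strand, ".", f"ID={mrna_id};Parent={gene_id}",
            ]))
            for k, (a, b) in enumerate(cds_intervals):
                phase = _phase_for(cds_intervals, strand, k)
                gff_rows.append("\t".join([
                    contig, "fixture", "exon", str(a + 1), str(b), ".",
                    strand, ".", f"ID={mrna_id}.e{k + 1};Parent={mrna_id}",
                ]))
                gff_rows.append("\t".join([
                    contig, "fixture", "CDS", str(a + 1), str(b), ".",
                    strand, str(phase), f"ID={mrna_id}.c{k + 1};Parent={mrna_id}",
                ]))
        contigs[contig] = seq

    # plant exact duplicates of the first gene's most start-proximal guide
    # locus into intergenic space (known off-target positives)
    planted: list[dict] = []
    if spec.planted_duplicates:
        first = truths[0]
        site = _first_guide_locus(
            "".join(contigs[first.contig]), first.start_codon
        )
        if site is None:
            raise FixtureError("no guide site near the first gene to duplicate")
        locus_23mer, site_info = site
        contig = f"chr{spec.n_contigs}"
        seq = contigs[contig]
        pos = len(seq) - 200
        for d in range(spec.planted_duplicates):
            start = pos - d * 50
            seq[start : start + 23] = list(locus_23mer)
            planted.append({
                "contig": contig, "start": start, "sequence": locus_23mer,
                "source_gene": first.gene_id, **site_info,
            })

    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for contig, seq in contigs.items():
            fh.write(f">{contig}\n")
            s = "".join(seq)
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")
    gff_path = out_dir / "genes.gff3"
    gff_path.write_text("\n".join(gff_rows) + "\n")
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(
        {"genes": [asdict(t) for t in truths], "planted": planted},
        indent=1, sort_keys=True,
    ))
    return MiniGenome(
        fasta=fasta_path, gff3=gff_path, truth=tuple(truths),
        planted=tuple(planted),
    )


def _phase_for(intervals: list[tuple[int, int]], strand: str, k: int) -> int:
    """GFF3 phase column for CDS piece k."""
    order = intervals if strand == "+" else intervals[::-1]
    idx = order.index(intervals[k])
    consumed = sum(b - a for a, b in order[:idx])
    return (3 - consumed % 3) % 3


def _first_guide_locus(seq: str, anchor: int) -> tuple[str, dict] | None:
    """The plus-strand 23-mer (protospacer+NGG) nearest the anchor, within
    60 bp, suitable for planting as an exact duplicate."""
    best = None
    for p in range(max(anchor - 60, 20), min(anchor + 60, len(seq) - 3)):
        if seq[p + 1 : p + 3] == "GG":
            locus = seq[p - 20 : p + 3]
            if "N" in locus:
                continue
            d = abs((p - 3) - anchor)
            if best is None or d < best[0]:
                best = (d, locus, p)
    if best is None:
        return None
    _, locus, p = best
    return locus, {"pam_start_source": p, "strand": "+"}
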