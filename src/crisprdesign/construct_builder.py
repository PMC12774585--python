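"""Donor-vector assembly, silent PAM mutation, Cre/LoxP simulation, and the
three annotated cloning maps emitted per design.

A design produces:

1. a guide-RNA vector map — the U6 expression vector after simulated BbsI
   golden-gate insertion of the annealed guide oligos;
2. an unaltered map of the genomic locus; and
3. an edited map — the locus with the chosen cassette inserted (tagging) or
   replacing the inter-cut span (deletion), homology arms annotated and
   PAM-disrupted by silent mutation, plus the full circular donor plasmid.

Tagging cassettes are inserted immediately after the start codon's ATG
(N-terminal) or immediately before the stop codon (C-terminal), so no
genomic base is lost. The 3xP3-DsRed screening marker between the two LoxP
sites is later excised in vivo by Cre; :func:`simulate_flox` reproduces the
excision and :func:`validate_frame` checks that the residual cassette plus
the retained 34-bp LoxP scar (used as a peptide linker) reads through in
frame with no premature stop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._vector_parts import LOXP, RESTRICTION_SITES
from .genome_io import GenomeAssembly, GeneModel, IsoformModel, extract_region, revcomp
from .guide_finder import GuideSite
from .maps import AssemblyMap, MapFeature, read_genbank, read_genbank_all, write_genbank
from .primer_design import PrimerCandidate, PrimerConfig, PrimerPair

__all__ = [
    "AssemblyMap",
    "DesignConfig",
    "DesignError",
    "DesignResult",
    "FrameReport",
    "HomologyArm",
    "MutationReport",
    "PamMutationError",
    "VectorTemplate",
    "build_deletion_maps",
    "build_tagging_maps",
    "design_guide_oligos",
    "extract_homology_arms",
    "get_vector",
    "load_builtin_vectors",
    "load_vector",
    "mutate_pam_silent",
    "read_genbank",
    "simulate_flox",
    "validate_frame",
    "write_genbank",
]

BUILTIN_VECTOR_NAMES = (
    "pHD-SspB-ExLK-EGFP-DsRed",
    "pHD-SspB-ExLK-mCherry-DsRed",
    "pHD-EGFP-ExLK-SspB-DsRed",
    "pHD-mCherry-ExLK-SspB-DsRed",
    "pHD-DsRed",
    "pHD-DsRed-attP",
    "pU6-BbsI-chiRNA",
)

_STOPS = {"TAA", "TAG", "TGA"}


class DesignError(ValueError):
    pass


class PamMutationError(DesignError):
    """No silent mutation can disrupt the guide target in the donor."""


class VectorError(DesignError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    """User-tunable design parameters (config file + CLI flags)."""

    arm_length: int = 1000
    guide_window: int = 20
    primer: PrimerConfig = field(default_factory=PrimerConfig)
    codon_table_id: int = 1
    vector: str | None = None
    fluorophore: str = "EGFP"
    terminus: str | None = None
    max_cut_distance: int = 10
    offtarget_max_mismatch: int = 3
    locus_pad: int = 1400

    def validate(self, for_tagging: bool = False) -> None:
        if self.arm_length < 0 or self.guide_window <= 0 or self.locus_pad <= 0:
            raise DesignError("lengths must be positive")
        if self.fluorophore not in ("EGFP", "mCherry"):
            raise DesignError(f"unknown fluorophore {self.fluorophore!r}")
        if for_tagging and self.terminus not in ("N", "C"):
            raise DesignError("terminus (N or C) is required for tagging")
        self.primer.validate()


# ---------------------------------------------------------------------------
# vector templates


@dataclass(frozen=True)
class VectorTemplate:
    """An annotated circular backbone with homology-arm slots.

    ``left_arm_slot`` / ``right_arm_slot`` are zero-length boundaries where
    arms are inserted; the payload between them (``insert span``) is what
    HDR copies into the genome. The internal representation keeps the
    rotation such that no built-in feature wraps the origin.
    """

    name: str
    sequence: str
    features: tuple[MapFeature, ...]
    kind: str  # tagging_N | tagging_C | deletion | guide | custom
    left_arm_slot: tuple[int, int] | None = None
    right_arm_slot: tuple[int, int] | None = None
    cassette_span: tuple[int, int] | None = None
    marker_span: tuple[int, int] | None = None
    loxp_spans: tuple[tuple[int, int], ...] = ()
    frame_offset: int = 0

    @property
    def insert_span(self) -> tuple[int, int]:
        if self.left_arm_slot is None or self.right_arm_slot is None:
            raise VectorError(f"vector {self.name} has no homology-arm slots")
        return (self.left_arm_slot[1], self.right_arm_slot[0])

    @property
    def insert_seq(self) -> str:
        a, b = self.insert_span
        return self.sequence[a:b]

    def insert_features(self) -> list[MapFeature]:
        a, b = self.insert_span
        return [
            f for f in self.features
            if a <= f.start and f.end <= b and f.type != "source"
            and (f.start, f.end) != (a, a) and (f.start, f.end) != (b, b)
        ]

    def to_map(self) -> AssemblyMap:
        return AssemblyMap(
            name=self.name,
            sequence=self.sequence,
            topology="circular",
            features=self.features,
            provenance_notes=tuple(
                v for f in self.features if f.type == "source"
                for k, v in f.qualifiers if k == "note"
            ),
        )


def template_from_map(amap: AssemblyMap, kind: str | None = None) -> VectorTemplate:
    """Build and invariant-check a :class:`VectorTemplate` from a map.

    Recognized labels: ``HA_left_slot``, ``HA_right_slot``, ``cassette``
    (with optional ``frame_offset`` qualifier), ``loxP`` (pair), plus
    arbitrary annotation. ``kind`` falls back to the source feature's
    ``vector_kind`` qualifier, then ``custom``.
    """
    if kind is None:
        for f in amap.features:
            if f.type == "source":
                kind = f.get("vector_kind")
                if kind:
                    break
        kind = kind or "custom"
    seq = amap.sequence

    def span_of(label: str) -> tuple[int, int] | None:
        hits = amap.features_labelled(label)
        return (hits[0].start, hits[0].end) if hits else None

    left = span_of("HA_left_slot")
    right = span_of("HA_right_slot")
    cassette = span_of("cassette")
    loxps = tuple((f.start, f.end) for f in amap.features_labelled("loxP"))
    frame_offset = 0
    cass_feats = amap.features_labelled("cassette")
    if cass_feats:
        frame_offset = int(cass_feats[0].get("frame_offset", "0"))

    if kind != "guide":
        if left is None or right is None:
            raise VectorError(
                f"vector {amap.name}: HA_left_slot / HA_right_slot features required"
            )
        if loxps:
            if len(loxps) != 2:
                raise VectorError(f"vector {amap.name}: expected 2 loxP features")
            s0, s1 = (seq[a:b] for a, b in loxps)
            f0, f1 = (f for f in amap.features if f.label == "loxP")
            if s0 != s1 or len(s0) != 34 or f0.strand != f1.strand:
                raise VectorError(
                    f"vector {amap.name}: loxP sites must be identical 34-bp "
                    "repeats in the same orientation"
                )
    marker = None
    if len(loxps) == 2:
        marker = (loxps[0][1], loxps[1][0])
    if kind in ("tagging_N", "tagging_C"):
        if cassette is None:
            raise VectorError(f"vector {amap.name}: tagging vector needs a cassette")
        cs = seq[cassette[0] + frame_offset : cassette[1]]
        for i in range(0, len(cs) - 2, 3):
            if cs[i : i + 3] in _STOPS:
                raise VectorError(
                    f"vector {amap.name}: cassette has an internal stop at "
                    f"offset {i} in register {frame_offset}"
                )
    return VectorTemplate(
        name=amap.name,
        sequence=seq,
        features=amap.features,
        kind=kind,
        left_arm_slot=left,
        right_arm_slot=right,
        cassette_span=cassette,
        marker_span=marker,
        loxp_spans=loxps,
        frame_offset=frame_offset,
    )


def load_builtin_vectors() -> list[VectorTemplate]:
    """Load and invariant-check the seven packaged vector templates."""
    out = []
    base = resources.files("crisprdesign").joinpath("data/vectors")
    for name in BUILTIN_VECTOR_NAMES:
        fname = re.sub(r"[^A-Za-z0-9]", "_", name) + ".gb"
        with resources.as_file(base.joinpath(fname)) as path:
            out.append(template_from_map(read_genbank(path)))
    return out


def get_vector(name: str) -> VectorTemplate:
    for vec in load_builtin_vectors():
        if vec.name == name:
            return vec
    raise VectorError(
        f"unknown built-in vector {name!r}; available: {list(BUILTIN_VECTOR_NAMES)}"
    )


def load_vector(name_or_path: str, kind: str | None = None) -> VectorTemplate:
    """A built-in vector by name, or a user GenBank file by path."""
    if name_or_path in BUILTIN_VECTOR_NAMES:
        return get_vector(name_or_path)
    path = Path(name_or_path)
    if not path.exists():
        raise VectorError(
            f"{name_or_path!r} is neither a built-in vector name nor a file"
        )
    return template_from_map(read_genbank(path), kind=kind)


# ---------------------------------------------------------------------------
# homology arms


@dataclass(frozen=True)
class HomologyArm:
    """A plus-strand genomic substring serving as an HDR arm."""

    seq: str
    contig: str
    start: int
    end: int
    side: str  # left | right
    shortened: bool = False

    def mutated(self, substitutions: dict[int, str]) -> "HomologyArm":
        chars = list(self.seq)
        for pos, base in substitutions.items():
            if self.start <= pos < self.end:
                chars[pos - self.start] = base
        return replace(self, seq="".join(chars))


def extract_homology_arms(
    assembly: GenomeAssembly,
    contig: str,
    anchor: int | tuple[int, int],
    arm_length: int,
) -> tuple[HomologyArm, HomologyArm, list[str]]:
    """Arms flanking a single insertion point or a (cutN, cutC) pair.

    The left arm ends at the insertion point (or N-terminal cut), the right
    arm starts at it (or at the C-terminal cut). Arms running off the
    contig are shortened with a warning. Arms containing N are rejected.
    """
    if isinstance(anchor, tuple):
        left_edge, right_edge = anchor
        if left_edge >= right_edge:
            raise DesignError(
                f"cut positions must satisfy cutN < cutC, got {anchor}"
            )
    else:
        left_edge = right_edge = anchor
    n = assembly.length(contig)
    if not (0 <= left_edge <= right_edge <= n):
        raise DesignError(f"anchor {anchor} outside contig {contig!r}")
    warnings_: list[str] = []
    ls = left_edge - arm_length
    if ls < 0:
        warnings_.append(f"left arm shortened to {left_edge} bp (contig start)")
        ls = 0
    re_ = right_edge + arm_length
    if re_ > n:
        warnings_.append(f"right arm shortened to {n - right_edge} bp (contig end)")
        re_ = n
    left = HomologyArm(
        seq=extract_region(assembly, contig, ls, left_edge),
        contig=contig, start=ls, end=left_edge, side="left",
        shortened=ls != left_edge - arm_length,
    )
    right = HomologyArm(
        seq=extract_region(assembly, contig, right_edge, re_),
        contig=contig, start=right_edge, end=re_, side="right",
        shortened=re_ != right_edge + arm_length,
    )
    if arm_length == 0:
        warnings_.append("arm_length 0: empty homology arms (degenerate design)")
    for arm in (left, right):
        if "N" in arm.seq:
            raise DesignError(
                f"{arm.side} homology arm [{arm.start}, {arm.end}) contains N; "
                "ambiguous bases invalidate designs"
            )
    return left, right, warnings_


# ---------------------------------------------------------------------------
# silent PAM mutation


@dataclass(frozen=True)
class Substitution:
    genomic_pos: int
    ref: str   # plus-strand base before
    alt: str   # plus-strand base after
    codon_before: str | None
    codon_after: str | None
    amino_acid: str | None
    context: str  # PAM | seed | non-coding


@dataclass(frozen=True)
class MutationReport:
    substitutions: tuple[Substitution, ...]
    strategy: str  # pam-synonymous | seed-synonymous | non-coding | not-needed
    note: str = ""


def _transcript_offset(iso: IsoformModel, strand: str, pos: int) -> int | None:
    """Transcript-order CDS offset of plus-strand position *pos*, or None."""
    if strand == "+":
        off = 0
        for s, e in iso.cds:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None
    off = 0
    for s, e in reversed(iso.cds):
        if s <= pos < e:
            return off + (e - 1 - pos)
        off += e - s
    return None


def _genomic_pos_of_offset(iso: IsoformModel, strand: str, off: int) -> int:
    if strand == "+":
        for s, e in iso.cds:
            if off < e - s:
                return s + off
            off -= e - s
    else:
        for s, e in reversed(iso.cds):
            if off < e - s:
                return e - 1 - off
            off -= e - s
    raise IndexError("CDS offset out of range")


def _codon_state(
    iso: IsoformModel, strand: str, pos: int, genome_base: dict[int, str]
) -> tuple[int, int, list[int], str] | None:
    """(codon_index, within, genomic positions in transcript order, codon)."""
    off = _transcript_offset(iso, strand, pos)
    if off is None:
        return None
    ci, within = divmod(off, 3)
    gpos = [_genomic_pos_of_offset(iso, strand, ci * 3 + k) for k in range(3)]
    bases = [genome_base[g] for g in gpos]
    if strand == "-":
        bases = [revcomp(b) for b in bases]
    return ci, within, gpos, "".join(bases)


def _synonymous_alternatives(codon: str, table_id: int) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    if codon in table.stop_codons:
        return []
    aa = table.forward_table[codon]
    return sorted(
        c for c in table.forward_table
        if table.forward_table[c] == aa and c != codon
    )


def mutate_pam_silent(
    arm: HomologyArm,
    guide: GuideSite,
    isoform: IsoformModel,
    strand: str,
    codon_table: int = 1,
) -> tuple[HomologyArm, MutationReport]:
    """Disrupt the guide target inside a homology arm without changing the
    encoded protein.

    Priority: (1) a synonymous single-base change that breaks the PAM's GG;
    (2) if the PAM lies outside annotated CDS, a direct G→T (guide-strand)
    substitution; (3) synonymous changes in the PAM-proximal 10-nt seed
    (two preferred, one accepted). If nothing silent disrupts the target a
    :class:`PamMutationError` tells the user to pick another guide.
    """
    genome_base = {arm.start + i: b for i, b in enumerate(arm.seq)}
    # plus-strand positions of the PAM's two G bases (guide-strand reading)
    if guide.strand == "+":
        gg = [guide.pam_start + 1, guide.pam_start + 2]
        disrupt_ok = lambda plus_base: plus_base != "G"  # noqa: E731
        direct_alt = "T"
    else:
        gg = [guide.pam_start - 2, guide.pam_start - 1]
        disrupt_ok = lambda plus_base: plus_base != "C"  # noqa: E731
        direct_alt = "A"  # G→T on the guide strand

    def in_arm(pos: int) -> bool:
        return arm.start <= pos < arm.end

    # --- priority 1: synonymous PAM disruption -----------------------------
    for pos in sorted(gg):
        if not in_arm(pos):
            continue
        state = _codon_state(isoform, strand, pos, genome_base)
        if state is None:
            continue
        _, within, gpos, codon = state
        idx = gpos.index(pos)
        for alt_codon in _synonymous_alternatives(codon, codon_table):
            if sum(a != b for a, b in zip(alt_codon, codon)) != 1:
                continue
            if alt_codon[idx] == codon[idx]:
                continue
            new_tx_base = alt_codon[idx]
            new_plus = new_tx_base if strand == "+" else revcomp(new_tx_base)
            if not disrupt_ok(new_plus):
                continue
            table = CodonTable.unambiguous_dna_by_id[codon_table]
            sub = Substitution(
                genomic_pos=pos, ref=genome_base[pos], alt=new_plus,
                codon_before=codon, codon_after=alt_codon,
                amino_acid=table.forward_table[codon], context="PAM",
            )
            return (
                arm.mutated({pos: new_plus}),
                MutationReport((sub,), "pam-synonymous"),
            )

    # --- priority 2: PAM outside CDS → direct disruption -------------------
    noncoding_gg = [
        pos for pos in sorted(gg)
        if in_arm(pos) and _transcript_offset(isoform, strand, pos) is None
    ]
    if noncoding_gg:
        pos = noncoding_gg[0]
        sub = Substitution(
            genomic_pos=pos, ref=genome_base[pos], alt=direct_alt,
            codon_before=None, codon_after=None, amino_acid=None,
            context="non-coding",
        )
        return (
            arm.mutated({pos: direct_alt}),
            MutationReport((sub,), "non-coding",
                           note="PAM base outside annotated CDS"),
        )

    # --- priority 3: synonymous seed mutations -----------------------------
    if guide.strand == "+":
        seed = list(range(guide.pam_start - 1, guide.pam_start - 11, -1))
    else:
        seed = list(range(guide.pam_start + 1, guide.pam_start + 11))
    subs: list[Substitution] = []
    table = CodonTable.unambiguous_dna_by_id[codon_table]
    transversion = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for pos in seed:  # PAM-proximal first
        if len(subs) >= 2:
            break
        if not in_arm(pos):
            continue
        state = _codon_state(isoform, strand, pos, genome_base)
        if state is None:
            # outside annotated CDS: any base change is silent
            new_plus = transversion[genome_base[pos]]
            subs.append(Substitution(
                genomic_pos=pos, ref=genome_base[pos], alt=new_plus,
                codon_before=None, codon_after=None, amino_acid=None,
                context="seed",
            ))
            genome_base[pos] = new_plus
            continue
        _, within, gpos, codon = state
        idx = gpos.index(pos)
        for alt_codon in _synonymous_alternatives(codon, codon_table):
            if sum(a != b for a, b in zip(alt_codon, codon)) != 1:
                continue
            if alt_codon[idx] == codon[idx]:
                continue
            new_tx_base = alt_codon[idx]
            new_plus = new_tx_base if strand == "+" else revcomp(new_tx_base)
            subs.append(Substitution(
                genomic_pos=pos, ref=genome_base[pos], alt=new_plus,
                codon_before=codon, codon_after=alt_codon,
                amino_acid=table.forward_table[codon], context="seed",
            ))
            genome_base[pos] = new_plus
            break
    if subs:
        note = "" if len(subs) >= 2 else "only one synonymous seed change available"
        return (
            arm.mutated({s.genomic_pos: s.alt for s in subs}),
            MutationReport(tuple(subs), "seed-synonymous", note=note),
        )
    raise PamMutationError(
        f"no silent mutation can disrupt guide at PAM {guide.pam_start} "
        f"({guide.strand}); pick another guide"
    )


def _exact_site_present(seq: str, guide: GuideSite) -> bool:
    """Does *seq* contain the protospacer with an NGG PAM on either strand?"""
    for s in (seq, revcomp(seq)):
        start = 0
        while True:
            i = s.find(guide.protospacer, start)
            if i < 0:
                break
            if i + 23 <= len(s) and s[i + 21 : i + 23] == "GG":
                return True
            start = i + 1
    return False


# ---------------------------------------------------------------------------
# map assembly helpers


def _primer_features(
    pairs: list[PrimerPair] | None,
    singles: list[PrimerCandidate] | None,
    offset: int,
) -> list[MapFeature]:
    feats = []
    cands: list[tuple[PrimerCandidate, str]] = []
    if pairs:
        best = pairs[0]
        cands += [(best.forward, "amplification F"), (best.reverse, "amplification R")]
    if singles:
        seen = set()
        for c in singles:
            if c.side not in seen:
                seen.add(c.side)
                cands.append((c, f"sequencing {c.side}"))
    for cand, tag in cands:
        s, e = cand.span
        feats.append(MapFeature(
            s - offset, e - offset, 1 if cand.strand == "+" else -1,
            "primer_bind", f"{tag} primer",
            (("note", f"Tm {cand.tm:.1f} C, {cand.sequence}"),),
        ))
    return feats


def _guide_feature(guide: GuideSite, offset: int, note: str = "") -> MapFeature:
    if guide.strand == "+":
        s, e = guide.pam_start - 20, guide.pam_start + 3
    else:
        s, e = guide.pam_start - 2, guide.pam_start + 21
    quals = [("note", f"protospacer {guide.protospacer} PAM {guide.pam}")]
    if note:
        quals.append(("note", note))
    return MapFeature(
        s - offset, e - offset, 1 if guide.strand == "+" else -1,
        "misc_bind", "guide target", tuple(quals),
    )


def _gene_features(
    gene: GeneModel, iso: IsoformModel, offset: int
) -> list[MapFeature]:
    strand = 1 if gene.strand == "+" else -1
    feats = [MapFeature(
        min(s for s, _ in iso.exons) - offset,
        max(e for _, e in iso.exons) - offset,
        strand, "gene", gene.symbol, (("gene_id", gene.gene_id),),
    )]
    for s, e in iso.cds:
        feats.append(MapFeature(
            s - offset, e - offset, strand, "CDS", f"{iso.isoform_id} CDS",
            (("isoform", iso.isoform_id),),
        ))
    return feats


def _split_and_shift(
    feats: list[MapFeature], point: int, ins_len: int
) -> list[MapFeature]:
    """Shift map features past an insertion at *point*, splitting spanners."""
    out = []
    for f in feats:
        if f.end <= point:
            out.append(f)
        elif f.start >= point:
            out.append(f.shifted(ins_len))
        else:
            out.append(replace(f, end=point))
            out.append(replace(f, start=point + ins_len, end=f.end + ins_len))
    return out


def _delete_and_shift(
    feats: list[MapFeature], dstart: int, dend: int, ins_len: int
) -> list[MapFeature]:
    """Rewrite features around a deletion [dstart, dend) replaced by an
    insert of *ins_len*; features inside the deletion are dropped, spanners
    truncated."""
    shift = ins_len - (dend - dstart)
    out = []
    for f in feats:
        if f.end <= dstart:
            out.append(f)
        elif f.start >= dend:
            out.append(f.shifted(shift))
        elif f.start < dstart and f.end > dend:
            out.append(replace(f, end=f.end + shift))
        elif f.start < dstart:
            out.append(replace(f, end=dstart))
        elif f.end > dend:
            out.append(replace(f, start=dstart + ins_len, end=f.end + shift))
        # else fully inside: dropped
    return out


def _oriented_insert(
    vector: VectorTemplate, gene_strand: str
) -> tuple[str, list[MapFeature]]:
    """The vector payload and its features, flipped for minus-strand genes."""
    a, _ = vector.insert_span
    seq = vector.insert_seq
    feats = [
        replace(f.shifted(-a), qualifiers=f.qualifiers + (("inserted", "vector"),))
        for f in vector.insert_features()
    ]
    if gene_strand == "-":
        n = len(seq)
        seq = revcomp(seq)
        feats = [
            replace(f, start=n - f.end, end=n - f.start, strand=-f.strand)
            for f in feats
        ]
    return seq, feats


# ---------------------------------------------------------------------------
# flox simulation and frame validation


class FloxError(DesignError):
    pass


def simulate_flox(amap: AssemblyMap) -> AssemblyMap:
    """Cre/LoxP excision: remove everything between the starts of the two
    identical same-orientation LoxP sites, leaving a single 34-bp LoxP."""
    loxps = sorted(amap.features_labelled("loxP"), key=lambda f: f.start)
    if len(loxps) != 2:
        raise FloxError(
            f"flox needs exactly 2 loxP features, found {len(loxps)}"
        )
    a, b = loxps
    sa = amap.sequence[a.start : a.end]
    sb = amap.sequence[b.start : b.end]
    if sa != sb or len(sa) != 34:
        raise FloxError("loxP sites are not identical 34-bp repeats")
    if a.strand != b.strand:
        raise FloxError(
            "loxP sites are inverted; Cre inversion is not simulated"
        )
    dstart, dend = a.start, b.start
    new_seq = amap.sequence[:dstart] + amap.sequence[dend:]
    new_feats = _delete_and_shift(
        [f for f in amap.features], dstart, dend, 0
    )
    return AssemblyMap(
        name=amap.name,
        sequence=new_seq,
        topology=amap.topology,
        features=tuple(new_feats),
        provenance_notes=amap.provenance_notes
        + (f"Cre/LoxP excision removed [{dstart}, {dend}); one loxP retained",),
    )


@dataclass(frozen=True)
class FrameReport:
    passes: bool
    inserted_length: int
    frame_offset: int
    premature_stop: bool
    junction_peptide: str
    message: str = ""


def validate_frame(
    floxed_map: AssemblyMap, isoform: IsoformModel | None = None,
    terminus: str | None = None, codon_table: int = 1,
) -> FrameReport:
    """Translate from the isoform ATG through the residual cassette (and
    the retained LoxP linker) into the downstream CDS.

    Passes iff the total inserted length is a multiple of 3 and the fused
    reading frame reaches the natural stop without a premature stop. The
    report carries the fusion-junction peptide.
    """
    cds_feats = sorted(
        (f for f in floxed_map.features if f.type == "CDS" and
         f.get("isoform") is not None),
        key=lambda f: f.start,
    )
    ins_feats = [f for f in floxed_map.features if f.get("inserted") == "vector"]
    if not cds_feats or not ins_feats:
        raise DesignError("map lacks CDS or inserted-cassette annotations")
    ins_span = (min(f.start for f in ins_feats), max(f.end for f in ins_feats))
    ins_len = ins_span[1] - ins_span[0]
    strand = cds_feats[0].strand
    segments = [(f.start, f.end) for f in cds_feats] + [ins_span]
    segments.sort()
    if strand == -1:
        segments = segments[::-1]
    spliced = "".join(
        extract_region(
            GenomeAssembly({"m": floxed_map.sequence}), "m", s, e,
            "+" if strand == 1 else "-",
        )
        for s, e in segments
    )
    table = CodonTable.unambiguous_dna_by_id[codon_table]
    frame_offset = ins_len % 3
    # transcript offset at which the insert begins
    tx_off = 0
    for s, e in segments:
        if (s, e) == ins_span:
            break
        tx_off += e - s
    aa = str(Seq(spliced[: len(spliced) - len(spliced) % 3]).translate(table=table))
    n_codons = len(aa)
    premature = "*" in aa[: n_codons - 1]
    ends_with_stop = aa.endswith("*")
    lo = max(0, tx_off // 3 - 5)
    hi = min(n_codons, -(-(tx_off + ins_len) // 3) + 5)
    junction = aa[lo:hi]
    passes = frame_offset == 0 and not premature and ends_with_stop
    msg = []
    if frame_offset:
        msg.append(f"inserted length {ins_len} not a multiple of 3 "
                   f"(frame offset {frame_offset})")
    if premature:
        msg.append("premature stop codon in fusion reading frame")
    if not ends_with_stop:
        msg.append("fusion does not terminate at the natural stop codon")
    return FrameReport(
        passes=passes,
        inserted_length=ins_len,
        frame_offset=frame_offset,
        premature_stop=premature,
        junction_peptide=junction,
        message="; ".join(msg) or "in frame",
    )


# ---------------------------------------------------------------------------
# guide oligos and golden-gate simulation

_BBSI_F = RESTRICTION_SITES["BbsI"]       # GAAGAC
_BBSI_R = revcomp(_BBSI_F)                # GTCTTC


def design_guide_oligos(
    guide: GuideSite, guide_vector: VectorTemplate
) -> tuple[str, str, AssemblyMap]:
    """Annealable BbsI golden-gate oligos and the assembled guide vector.

    Forward oligo: ``CTTCG`` + protospacer (the leading overhang supplies
    the G required by the U6 promoter; a protospacer already starting with
    G contributes only its last 19 bases). Reverse oligo: ``AAAC`` +
    reverse complement of the spacer + ``C``. Simulated BbsI digestion of
    the vector followed by ligation reconstructs the circular guide map
    with the spacer in the slot and no residual BbsI site.
    """
    proto = guide.protospacer
    spacer = proto[1:] if proto.startswith("G") else proto
    forward = "CTTCG" + spacer
    reverse = "AAAC" + revcomp(spacer) + "C"

    seq = guide_vector.sequence
    top_sites = [m.start() for m in re.finditer(_BBSI_F, seq)]
    bottom_sites = [m.start() for m in re.finditer(_BBSI_R, seq)]
    if len(top_sites) + len(bottom_sites) != 2:
        raise VectorError(
            f"guide vector {guide_vector.name} must carry exactly two BbsI "
            f"sites, found {len(top_sites) + len(bottom_sites)}"
        )
    # cut boundaries (top-strand coordinate, bottom = top+4 for 5' overhangs)
    cuts = sorted(
        [s + 8 for s in top_sites] + [s - 6 for s in bottom_sites]
    )
    t1, t2 = cuts  # stuffer = [t1, t2) given outward-facing sites
    if not all(t1 <= s < t2 for s in top_sites + bottom_sites):
        raise VectorError(
            f"guide vector {guide_vector.name}: BbsI sites do not face the "
            "cloning slot"
        )
    left_ovh = seq[t1 : t1 + 4]   # pairs with the forward oligo's 5' overhang
    right_ovh = seq[t2 : t2 + 4]  # backbone's own 5' overhang at the slot end
    if left_ovh != forward[:4]:
        raise VectorError(
            f"vector overhang {left_ovh} does not match oligo overhang "
            f"{forward[:4]}"
        )
    if right_ovh != revcomp(reverse[:4]):
        raise VectorError(
            f"vector overhang {right_ovh} does not match oligo overhang "
            f"{reverse[:4]}"
        )
    product_seq = seq[:t1] + forward + seq[t2:]
    notes = [f"BbsI golden-gate insertion of guide oligos for {proto}"]
    # the vector's own BbsI sites must be destroyed; a motif contributed by
    # the spacer itself is a cloning caveat (risk of re-cutting in one-pot
    # assembly), recorded as a note rather than an error
    ins_lo, ins_hi = t1 - 5, t1 + len(forward) + 5
    for motif in (_BBSI_F, _BBSI_R):
        pos = product_seq.find(motif)
        while pos >= 0:
            if ins_lo <= pos <= ins_hi:
                notes.append(
                    f"WARNING: spacer region contains a BbsI motif at {pos}; "
                    "avoid one-pot golden-gate re-digestion"
                )
            else:
                raise VectorError(
                    "vector BbsI site survived golden-gate assembly"
                )
            pos = product_seq.find(motif, pos + 1)
    if product_seq.count(proto) + revcomp(product_seq).count(proto) != 1:
        raise VectorError("protospacer not unique in assembled guide vector")

    ins_len = len(forward)
    feats = [
        f for f in guide_vector.features
        if f.end <= t1 or f.start >= t2 or f.type == "source"
    ]
    new_feats = []
    for f in feats:
        if f.type == "source":
            new_feats.append(replace(f, end=len(product_seq)))
        elif f.start >= t2:
            new_feats.append(f.shifted(ins_len - (t2 - t1)))
        else:
            new_feats.append(f)
    # with a G-starting protospacer the overhang's G is the spacer's first base
    spacer_start = t1 + 4 if proto.startswith("G") else t1 + 5
    new_feats.append(MapFeature(
        spacer_start, t1 + len(forward), 1, "misc_RNA", "protospacer",
        (("note", f"guide spacer {proto}"),),
    ))
    amap = AssemblyMap(
        name=f"{guide_vector.name}::{proto[:8]}",
        sequence=product_seq,
        topology="circular",
        features=tuple(new_feats),
        provenance_notes=tuple(notes),
    )
    return forward, reverse, amap


# ---------------------------------------------------------------------------
# top-level map builders


@dataclass(frozen=True)
class DesignResult:
    guide_maps: tuple[AssemblyMap, ...]
    locus_map: AssemblyMap
    edited_map: AssemblyMap
    donor_map: AssemblyMap
    oligos: tuple[tuple[str, str], ...]
    mutation_reports: tuple[MutationReport, ...]
    frame_report: FrameReport | None
    warnings: tuple[str, ...]

    @property
    def guide_map(self) -> AssemblyMap:
        return self.guide_maps[0]


def _locus_bounds(
    assembly: GenomeAssembly, gene: GeneModel, iso: IsoformModel,
    config: DesignConfig,
) -> tuple[int, int]:
    pad = max(config.arm_length, config.locus_pad)
    lo = min(s for s, _ in iso.exons) - pad
    hi = max(e for _, e in iso.exons) + pad
    return max(lo, 0), min(hi, assembly.length(gene.contig))


def _build_locus_map(
    assembly: GenomeAssembly, gene: GeneModel, iso: IsoformModel,
    lo: int, hi: int,
    guides: list[GuideSite],
    pairs: list[PrimerPair] | None,
    seq_primers: list[PrimerCandidate] | None,
) -> AssemblyMap:
    feats = _gene_features(gene, iso, lo)
    for g in guides:
        feats.append(_guide_feature(g, lo))
    feats += _primer_features(pairs, seq_primers, lo)
    return AssemblyMap(
        name=f"{gene.gene_id}_locus",
        sequence=extract_region(assembly, gene.contig, lo, hi),
        topology="linear",
        features=tuple(sorted(feats, key=lambda f: (f.start, f.end, f.label))),
        provenance_notes=(
            f"unaltered locus {gene.contig}:{lo}-{hi} (0-based half-open)",
        ),
    )


def _donor_map(
    vector: VectorTemplate, left_donor: str, right_donor: str, gene_id: str,
) -> AssemblyMap:
    ls, le = vector.left_arm_slot
    rs, rend = vector.right_arm_slot
    seq = (
        vector.sequence[:ls] + left_donor + vector.sequence[le:rs]
        + right_donor + vector.sequence[rend:]
    )
    d1 = len(left_donor) - (le - ls)
    d2 = len(right_donor) - (rend - rs)
    feats = []
    for f in vector.features:
        if f.type == "source":
            feats.append(replace(f, end=len(seq)))
        elif f.end <= ls:
            feats.append(f)
        elif f.start >= rend:
            feats.append(f.shifted(d1 + d2))
        elif le <= f.start and f.end <= rs:
            feats.append(f.shifted(d1))
        # features overlapping the slots themselves are dropped
    feats.append(MapFeature(ls, ls + len(left_donor), 1, "misc_feature",
                            "HA_left", (("gene_id", gene_id),)))
    feats.append(MapFeature(rs + d1, rs + d1 + len(right_donor), 1,
                            "misc_feature", "HA_right", (("gene_id", gene_id),)))
    return AssemblyMap(
        name=f"{vector.name}::{gene_id}",
        sequence=seq,
        topology="circular",
        features=tuple(sorted(feats, key=lambda f: (f.start, f.end, f.label))),
        provenance_notes=(f"donor: {vector.name} with {gene_id} homology arms",),
    )


def build_tagging_maps(
    assembly: GenomeAssembly,
    gene: GeneModel,
    iso: IsoformModel,
    terminus: str,
    guide: GuideSite,
    vector: VectorTemplate,
    guide_vector: VectorTemplate,
    config: DesignConfig | None = None,
    pairs: list[PrimerPair] | None = None,
    seq_primers: list[PrimerCandidate] | None = None,
) -> DesignResult:
    """Assemble the three maps for an endogenous-tagging design.

    The cassette is inserted immediately after the start codon's ATG
    (terminus 'N') or immediately before the stop codon ('C'); no genomic
    base is deleted, so ``len(edited) = len(locus) + len(insert)``.
    """
    config = config or DesignConfig(terminus=terminus)
    config.validate(for_tagging=True)
    if terminus not in ("N", "C"):
        raise DesignError("terminus must be 'N' or 'C'")
    if vector.kind not in (f"tagging_{terminus}", "custom"):
        raise DesignError(
            f"vector {vector.name} (kind {vector.kind}) does not match "
            f"terminus {terminus}"
        )
    warnings_: list[str] = []
    if terminus == "N":
        b = iso.start_codon + 3 if gene.strand == "+" else iso.start_codon - 2
    else:
        b = iso.stop_codon if gene.strand == "+" else iso.stop_codon + 1
    dist = abs(guide.cut_pos - b)
    if dist > config.max_cut_distance:
        warnings_.append(
            f"guide cut is {dist} bp from the insertion point "
            f"(threshold {config.max_cut_distance}); re-cutting and repair "
            "fidelity may suffer"
        )
    lo, hi = _locus_bounds(assembly, gene, iso, config)
    left, right, arm_warnings = extract_homology_arms(
        assembly, gene.contig, b, config.arm_length
    )
    warnings_ += arm_warnings

    ins_seq, ins_feats = _oriented_insert(vector, gene.strand)
    ilen = len(ins_seq)

    # silent PAM mutation where the guide target survives intact in an arm
    gs, ge = (guide.pam_start - 20, guide.pam_start + 3) if guide.strand == "+" \
        else (guide.pam_start - 2, guide.pam_start + 21)
    reports: list[MutationReport] = []
    subs: dict[int, str] = {}
    # mutation is needed iff the guide target survives intact in the donor
    # (fully inside one arm, or reconstituted across an arm/insert junction)
    donor_context = left.seq + ins_seq + right.seq
    target_arm = None
    if _exact_site_present(donor_context, guide):
        overlaps = [
            (max(0, min(ge, arm.end) - max(gs, arm.start)), i, arm)
            for i, arm in enumerate((left, right))
        ]
        target_arm = max(overlaps)[2]
    if target_arm is not None:
        mutated, report = mutate_pam_silent(
            target_arm, guide, iso, gene.strand, config.codon_table_id
        )
        reports.append(report)
        subs = {
            s.genomic_pos: s.alt for s in report.substitutions
        }
        if target_arm.side == "left":
            left = mutated
        else:
            right = mutated
    else:
        reports.append(MutationReport(
            (), "not-needed",
            note="guide target spans the insertion point; cassette insertion "
                 "itself disrupts it",
        ))

    locus_map = _build_locus_map(
        assembly, gene, iso, lo, hi, [guide], pairs, seq_primers
    )

    # edited genomic map
    locus_seq = list(locus_map.sequence)
    for pos, base in subs.items():
        locus_seq[pos - lo] = base
    mutated_locus = "".join(locus_seq)
    edited_seq = mutated_locus[: b - lo] + ins_seq + mutated_locus[b - lo :]
    feats = _gene_features(gene, iso, lo)
    feats += _primer_features(pairs, seq_primers, lo)
    feats = _split_and_shift(feats, b - lo, ilen)
    feats += [f.shifted(b - lo) for f in ins_feats]
    feats.append(MapFeature(
        b - lo - len(left.seq), b - lo, 1, "misc_feature", "HA_left",
        (("gene_id", gene.gene_id),),
    ))
    feats.append(MapFeature(
        b - lo + ilen, b - lo + ilen + len(right.seq), 1, "misc_feature",
        "HA_right", (("gene_id", gene.gene_id),),
    ))
    for rep in reports:
        for s in rep.substitutions:
            p = s.genomic_pos - lo
            if s.genomic_pos >= b:
                p += ilen
            feats.append(MapFeature(
                p, p + 1, 1, "variation", "silent mutation",
                (("note",
                  f"{s.ref}->{s.alt} ({s.context}; codon "
                  f"{s.codon_before}->{s.codon_after}, {s.amino_acid})"
                  if s.codon_before else f"{s.ref}->{s.alt} ({s.context})"),),
            ))
    edited_map = AssemblyMap(
        name=f"{gene.gene_id}_edited",
        sequence=edited_seq,
        topology="linear",
        features=tuple(sorted(feats, key=lambda f: (f.start, f.end, f.label))),
        provenance_notes=(
            f"{vector.name} cassette inserted at {gene.contig}:{b} "
            f"({terminus}-terminal tagging of {gene.gene_id})",
        ),
    )

    # donor plasmid: arms in transcript orientation
    if gene.strand == "+":
        left_donor, right_donor = left.seq, right.seq
    else:
        left_donor, right_donor = revcomp(right.seq), revcomp(left.seq)
    donor = _donor_map(vector, left_donor, right_donor, gene.gene_id)
    if _exact_site_present(donor.sequence, guide):
        raise PamMutationError(
            "guide target still matches the donor exactly after mutation"
        )

    # frame validation on the floxed edited map (hard error on failure);
    # custom vectors without a LoxP pair are not floxable and skip the check
    frame = None
    if len(vector.loxp_spans) == 2:
        frame = validate_frame(
            simulate_flox(edited_map), iso, terminus, config.codon_table_id
        )
        if not frame.passes:
            raise DesignError(
                f"reading-frame violation after floxing: {frame.message}"
            )

    fwd, rev, guide_map = design_guide_oligos(guide, guide_vector)
    return DesignResult(
        guide_maps=(guide_map,),
        locus_map=locus_map,
        edited_map=edited_map,
        donor_map=donor,
        oligos=((fwd, rev),),
        mutation_reports=tuple(reports),
        frame_report=frame,
        warnings=tuple(warnings_),
    )


def build_deletion_maps(
    assembly: GenomeAssembly,
    gene: GeneModel,
    iso: IsoformModel,
    guide_n: GuideSite,
    guide_c: GuideSite,
    vector: VectorTemplate,
    guide_vector: VectorTemplate,
    config: DesignConfig | None = None,
    pairs: list[PrimerPair] | None = None,
    seq_primers: list[PrimerCandidate] | None = None,
) -> DesignResult:
    """Assemble the three maps for a two-cut gene-deletion design.

    The span between the N′ and C′ cuts is replaced by the marker cassette:
    ``len(edited) = len(locus) − (cutC − cutN) + len(insert)``.
    """
    config = config or DesignConfig()
    config.validate()
    cut_n, cut_c = guide_n.cut_pos, guide_c.cut_pos
    if cut_n >= cut_c:
        raise DesignError(
            f"deletion cuts must satisfy cutN < cutC, got {cut_n} and {cut_c}"
        )
    lo, hi = _locus_bounds(assembly, gene, iso, config)
    left, right, arm_warnings = extract_homology_arms(
        assembly, gene.contig, (cut_n, cut_c), config.arm_length
    )
    warnings_ = list(arm_warnings)
    ins_seq = vector.insert_seq
    a0, _ = vector.insert_span
    ins_feats = [
        replace(f.shifted(-a0), qualifiers=f.qualifiers + (("inserted", "vector"),))
        for f in vector.insert_features()
    ]
    ilen = len(ins_seq)

    locus_map = _build_locus_map(
        assembly, gene, iso, lo, hi, [guide_n, guide_c], pairs, seq_primers
    )
    feats = _gene_features(gene, iso, lo)
    feats += _primer_features(pairs, seq_primers, lo)
    feats = _delete_and_shift(feats, cut_n - lo, cut_c - lo, ilen)
    feats += [f.shifted(cut_n - lo) for f in ins_feats]
    feats.append(MapFeature(
        cut_n - lo, cut_n - lo + ilen, 1, "misc_feature",
        f"deletion of {gene.gene_id}",
        (("note", f"replaced {gene.contig}:{cut_n}-{cut_c} "
                  f"({cut_c - cut_n} bp) with {vector.name} cassette"),),
    ))
    feats.append(MapFeature(
        cut_n - lo - len(left.seq), cut_n - lo, 1, "misc_feature", "HA_left",
        (("gene_id", gene.gene_id),),
    ))
    feats.append(MapFeature(
        cut_n - lo + ilen, cut_n - lo + ilen + len(right.seq), 1,
        "misc_feature", "HA_right", (("gene_id", gene.gene_id),),
    ))
    edited_seq = (
        locus_map.sequence[: cut_n - lo] + ins_seq + locus_map.sequence[cut_c - lo :]
    )
    edited_map = AssemblyMap(
        name=f"{gene.gene_id}_deleted",
        sequence=edited_seq,
        topology="linear",
        features=tuple(sorted(feats, key=lambda f: (f.start, f.end, f.label))),
        provenance_notes=(
            f"two-cut deletion of {gene.gene_id}: removed "
            f"{gene.contig}:{cut_n}-{cut_c}, inserted {vector.name} cassette",
        ),
    )
    donor = _donor_map(vector, left.seq, right.seq, gene.gene_id)
    for g in (guide_n, guide_c):
        if _exact_site_present(donor.sequence, g):
            raise PamMutationError(
                f"guide target at PAM {g.pam_start} still matches the donor"
            )
    oligos_and_maps = [design_guide_oligos(g, guide_vector)
                       for g in (guide_n, guide_c)]
    return DesignResult(
        guide_maps=tuple(m for _, _, m in oligos_and_maps),
        locus_map=locus_map,
        edited_map=edited_map,
        donor_map=donor,
        oligos=tuple((f, r) for f, r, _ in oligos_and_maps),
        mutation_reports=(MutationReport(
            (), "not-needed",
            note="both guide targets span the deletion junction",
        ),),
        frame_report=None,
        warnings=tuple(warnings_),
    )
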