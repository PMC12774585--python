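"""Deterministic construction of the built-in vector templates.

Every backbone, ORF, promoter and linker here is a SYNTHETIC stand-in with
the correct feature topology (cassette, LoxP pair, screening marker,
homology-arm slots, restriction-site bookkeeping); only LoxP, the sgRNA
scaffold and the restriction-site recognition motifs are canonical public
sequences. Users substitute real vector GenBank files for real cloning.

Reading-frame bookkeeping: the canonical 34-bp LoxP is stop-free only when
read from its first base (registers 1 and 2 contain TAA), and 34 is not a
multiple of 3. Tagging templates therefore keep every fusion cassette a
multiple of 3 (so LoxP is reached in register 0) and carry a 2-bp "CC"
frame spacer after the second LoxP, making the retained scar (LoxP + CC,
36 bp) a clean 12-codon linker: the template, not the frame validator,
absorbs the register.
"""

from __future__ import annotations

from .maps import AssemblyMap, MapFeature

LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"  # canonical 34-mer
FRAME_SPACER = "CC"
SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)
U6_TERMINATOR = "TTTTTTT"

RESTRICTION_SITES = {
    "NdeI": "CATATG",
    "PmeI": "GTTTAAAC",
    "MluI": "ACGCGT",
    "EcoRI": "GAATTC",
    "NotI": "GCGGCCGC",
    "AscI": "GGCGCGCC",
    "XhoI": "CTCGAG",
    "SrfI": "GCCCGGGC",
    "BglII": "AGATCT",
    "BbsI": "GAAGAC",
}

_STOPS = {"TAA", "TAG", "TGA"}

# codon pools for synthetic ORFs; chosen so no junction can spell a stop
# codon, a BbsI site (GAAGAC/GTCTTC) or a LoxP fragment
_POOL_A = ["GCT", "GAA", "AAA", "CTG", "GAT", "TCT", "GTT", "CCG", "ACT", "ATC"]
_POOL_B = ["CAG", "TGG", "TAC", "CGT", "AAC", "GGC", "CAT", "TTC", "GCA", "CTC"]


def _orf(n_codons: int, pool: list[str], phase: int = 0) -> str:
    """Deterministic stop-free open reading frame of *n_codons* codons."""
    codons = [pool[(phase + 3 * i + i * i) % len(pool)] for i in range(n_codons)]
    seq = "".join(codons)
    assert not any(seq[i : i + 3] in _STOPS for i in range(0, len(seq), 3))
    return seq


def _filler(n: int, phase: int = 0) -> str:
    """Deterministic non-coding filler (synthetic backbone/promoter DNA)."""
    alphabet = "ACGT"
    out = []
    x = phase * 7 + 13
    for _ in range(n):
        x = (x * 1103515245 + 12345) % (2**31)
        out.append(alphabet[(x >> 16) % 4])
    return "".join(out)


# --- named synthetic parts (lengths chosen to keep cassettes ≡ 0 mod 3) ---

SSPB_R73Q = _orf(117, _POOL_A, phase=0)          # 351 bp, ~13 kDa adaptor
EGFP = _orf(240, _POOL_B, phase=1)               # 720 bp
MCHERRY = _orf(240, _POOL_B, phase=5)            # 720 bp
GGS = "GGTGGCGGAGGTTCT"                          # GGGGS unit, 15 bp

# extended flexible linker: GGGGS - MluI(TR) - GGGGS - NdeI(HM), 42 bp
EXLK_N = GGS + RESTRICTION_SITES["MluI"] + GGS + RESTRICTION_SITES["NdeI"]
# PmeI register-1 junction after the FP: GGT TTA AAC (G-L-N), 9 bp
PMEI_JUNCTION = "G" + RESTRICTION_SITES["PmeI"]
# NotI junction ahead of the FP in C-terminal cassettes: GCG GCC GCA, 9 bp
NOTI_JUNCTION = RESTRICTION_SITES["NotI"] + "A"

P3X3_PROMOTER = _filler(150, phase=2)            # synthetic 3xP3 stand-in
DSRED = "ATG" + _orf(225, _POOL_B, phase=3) + "TAA"  # 684 bp marker ORF
MARKER_TERMINATOR = _filler(120, phase=4)
U6_PROMOTER = _filler(250, phase=6)              # synthetic U6 stand-in
ATTP = _filler(39, phase=8)                      # synthetic attP stand-in

_PROVENANCE = (
    "SYNTHETIC STAND-IN: backbone, ORFs, promoters and linkers are "
    "deterministic placeholder sequences with correct feature topology; "
    "only LoxP, the sgRNA scaffold and restriction-site motifs are "
    "canonical. Substitute a real vector GenBank file for wet-lab cloning."
)


def _fusion_cassette(terminus: str, fp: str) -> tuple[str, list[tuple[str, str, str]]]:
    """Cassette sequence + ordered (label, type, seq) parts for one terminus."""
    fp_seq = EGFP if fp == "EGFP" else MCHERRY
    if terminus == "N":
        parts = [
            ("SspB(R73Q)", "CDS", SSPB_R73Q),
            ("ExLK linker", "CDS", EXLK_N),
            (fp, "CDS", fp_seq),
            ("PmeI junction", "misc_feature", PMEI_JUNCTION),
        ]
    else:
        parts = [
            ("NotI junction", "misc_feature", NOTI_JUNCTION),
            (fp, "CDS", fp_seq),
            ("ExLK linker", "CDS", EXLK_N),
            ("SspB(R73Q)", "CDS", SSPB_R73Q),
        ]
    seq = "".join(p[2] for p in parts)
    assert len(seq) % 3 == 0
    assert not any(seq[i : i + 3] in _STOPS for i in range(0, len(seq), 3))
    return seq, parts


def _marker_parts() -> list[tuple[str, str, str]]:
    return [
        ("3xP3 promoter", "promoter", P3X3_PROMOTER),
        ("DsRed", "CDS", DSRED),
        ("marker terminator", "terminator", MARKER_TERMINATOR),
    ]


class _Builder:
    def __init__(self, name: str, kind: str):
        self.name = name
        self.kind = kind
        self.seq: list[str] = []
        self.pos = 0
        self.features: list[MapFeature] = []

    def add(self, seq: str, label: str | None = None, ftype: str = "misc_feature",
            strand: int = 1, quals: tuple[tuple[str, str], ...] = ()) -> tuple[int, int]:
        start = self.pos
        self.seq.append(seq)
        self.pos += len(seq)
        if label is not None:
            self.features.append(
                MapFeature(start, self.pos, strand, ftype, label, quals))
        return start, self.pos

    def mark(self, label: str, quals: tuple[tuple[str, str], ...] = ()) -> int:
        """Zero-length boundary feature (homology-arm slot)."""
        self.features.append(
            MapFeature(self.pos, self.pos, 1, "misc_feature", label, quals))
        return self.pos

    def site(self, enzyme: str) -> None:
        self.add(RESTRICTION_SITES[enzyme], f"{enzyme} site", "misc_feature")

    def build(self) -> AssemblyMap:
        sequence = "".join(self.seq)
        source = MapFeature(
            0, len(sequence), 1, "source", self.name,
            (("note", _PROVENANCE), ("vector_kind", self.kind)),
        )
        return AssemblyMap(
            name=self.name,
            sequence=sequence,
            topology="circular",
            features=(source, *self.features),
            provenance_notes=(_PROVENANCE,),
        )


def _backbone(b: _Builder, phase: int, length: int = 900) -> None:
    ori = _filler(300, phase=phase)
    amp = "ATG" + _orf((length - 420) // 3, _POOL_A, phase=phase + 1) + "TAA"
    pad = _filler(length - 300 - len(amp), phase=phase + 2)
    b.add(ori, "rep_origin (synthetic)", "rep_origin")
    b.add(amp, "AmpR (synthetic)", "CDS")
    b.add(pad)


def build_tagging_template(terminus: str, fp: str) -> AssemblyMap:
    if terminus == "N":
        name = f"pHD-SspB-ExLK-{fp}-DsRed"
    else:
        name = f"pHD-{fp}-ExLK-SspB-DsRed"
    b = _Builder(name, f"tagging_{terminus}")
    _backbone(b, phase=10)
    if terminus == "N":
        b.site("EcoRI")
        b.site("NotI")
    else:
        b.site("SrfI")
        b.site("EcoRI")
        b.site("NotI")
    b.mark("HA_left_slot")
    cassette_seq, parts = _fusion_cassette(terminus, fp)
    if terminus == "N":
        cs = b.pos
        for label, ftype, seq in parts:
            b.add(seq, label, ftype)
        b.features.append(MapFeature(cs, b.pos, 1, "misc_feature", "cassette",
                                     (("frame_offset", "0"),)))
        b.add(LOXP, "loxP", "protein_bind")
        for label, ftype, seq in _marker_parts():
            b.add(seq, label, ftype)
        b.add(LOXP, "loxP", "protein_bind")
        b.add(FRAME_SPACER, "frame_spacer", "misc_feature")
    else:
        b.add(LOXP, "loxP", "protein_bind")
        for label, ftype, seq in _marker_parts():
            b.add(seq, label, ftype)
        b.add(LOXP, "loxP", "protein_bind")
        b.add(FRAME_SPACER, "frame_spacer", "misc_feature")
        cs = b.pos
        for label, ftype, seq in parts:
            b.add(seq, label, ftype)
        b.features.append(MapFeature(cs, b.pos, 1, "misc_feature", "cassette",
                                     (("frame_offset", "0"),)))
    b.mark("HA_right_slot")
    if terminus == "N":
        b.site("AscI")
        b.site("XhoI")
    else:
        b.site("BglII")
        b.site("XhoI")
    b.add(_filler(200, phase=12))
    return b.build()


def build_deletion_template(with_attp: bool) -> AssemblyMap:
    name = "pHD-DsRed-attP" if with_attp else "pHD-DsRed"
    b = _Builder(name, "deletion")
    _backbone(b, phase=20)
    b.site("EcoRI")
    b.site("NotI")
    b.mark("HA_left_slot")
    cs = b.pos
    b.add(LOXP, "loxP", "protein_bind")
    for label, ftype, seq in _marker_parts():
        b.add(seq, label, ftype)
    b.add(LOXP, "loxP", "protein_bind")
    if with_attp:
        b.add(ATTP, "attP (synthetic)", "misc_recomb")
    b.features.append(MapFeature(cs, b.pos, 1, "misc_feature", "cassette",
                                 (("frame_offset", "0"),)))
    b.mark("HA_right_slot")
    b.site("AscI")
    b.site("XhoI")
    b.add(_filler(200, phase=22))
    return b.build()


def build_guide_template() -> AssemblyMap:
    b = _Builder("pU6-BbsI-chiRNA", "guide")
    _backbone(b, phase=30, length=600)
    b.add(U6_PROMOTER, "U6 promoter (synthetic)", "promoter")
    # BbsI golden-gate slot: digestion excises the stuffer and exposes a
    # CTTC-complementary overhang on the promoter side and a GTTT overhang
    # (the scaffold's first bases) on the scaffold side
    b.add("CTTC")
    b.add("AA")
    b.add("GTCTTC", "BbsI site", "misc_feature", strand=-1)
    b.add(_filler(30, phase=32), "stuffer", "misc_feature")
    b.add(RESTRICTION_SITES["BbsI"], "BbsI site", "misc_feature")
    b.add("AA")
    b.add(SGRNA_SCAFFOLD, "sgRNA scaffold", "misc_RNA")
    b.add(U6_TERMINATOR, "U6 terminator", "terminator")
    b.add(_filler(200, phase=34))
    amap = b.build()
    n_sites = amap.sequence.count("GAAGAC") + amap.sequence.count("GTCTTC")
    assert n_sites == 2, f"guide template must carry exactly 2 BbsI sites, got {n_sites}"
    return amap


def build_all_templates() -> list[AssemblyMap]:
    """The seven built-in vectors, in a fixed order."""
    return [
        build_tagging_template("N", "EGFP"),
        build_tagging_template("N", "mCherry"),
        build_tagging_template("C", "EGFP"),
        build_tagging_template("C", "mCherry"),
        build_deletion_template(with_attp=False),
        build_deletion_template(with_attp=True),
        build_guide_template(),
    ]
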