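"""Homology arms, silent PAM mutation, flox simulation, frame validation,
guide oligos, and the tagging/deletion map builders."""

import pytest
from Bio.Seq import Seq

from crisprdesign.construct_builder import (
    DesignError,
    FloxError,
    HomologyArm,
    PamMutationError,
    VectorError,
    build_deletion_maps,
    build_tagging_maps,
    design_guide_oligos,
    extract_homology_arms,
    get_vector,
    mutate_pam_silent,
    simulate_flox,
    template_from_map,
    validate_frame,
)
from crisprdesign.genome_io import GenomeAssembly, IsoformModel, revcomp
from crisprdesign.guide_finder import GuideSite, cut_position, scan_guides
from crisprdesign.maps import AssemblyMap, MapFeature, read_genbank, write_genbank


def make_guide(proto, pam, strand, pam_start, contig="c"):
    return GuideSite(
        protospacer=proto, pam=pam, strand=strand, contig=contig,
        pam_start=pam_start, cut_pos=cut_position(pam_start, strand),
        anchor_distance=0,
    )


class TestHomologyArms:
    def test_exact_kilobase_arms(self):
        seq = "".join("ACGT"[(i * 7 + 3) % 4] for i in range(10_000))
        a = GenomeAssembly({"c": seq})
        left, right, warns = extract_homology_arms(a, "c", 5000, 1000)
        assert (left.start, left.end) == (4000, 5000)
        assert (right.start, right.end) == (5000, 6000)
        assert left.seq == seq[4000:5000] and right.seq == seq[5000:6000]
        assert left.seq + right.seq == seq[4000:6000]
        assert warns == []

    def test_zero_length_arms_warn(self):
        a = GenomeAssembly({"c": "ACGT" * 100})
        left, right, warns = extract_homology_arms(a, "c", 200, 0)
        assert left.seq == right.seq == ""
        assert any("degenerate" in w for w in warns)

    def test_arm_shortened_at_contig_edge(self):
        a = GenomeAssembly({"c": "ACGT" * 200})
        left, _, warns = extract_homology_arms(a, "c", 100, 500)
        assert left.start == 0 and left.shortened
        assert any("shortened" in w for w in warns)

    def test_cut_pair_arms(self):
        a = GenomeAssembly({"c": "ACGT" * 3000})
        left, right, _ = extract_homology_arms(a, "c", (4000, 7000), 1000)
        assert (left.start, left.end) == (3000, 4000)
        assert (right.start, right.end) == (7000, 8000)

    def test_inverted_cuts_rejected(self):
        a = GenomeAssembly({"c": "ACGT" * 3000})
        with pytest.raises(DesignError):
            extract_homology_arms(a, "c", (7000, 4000), 1000)

    def test_n_in_arm_rejected(self):
        a = GenomeAssembly({"c": "ACGT" * 50 + "N" + "ACGT" * 50})
        with pytest.raises(DesignError, match="contains N"):
            extract_homology_arms(a, "c", 200, 100)


def _mutation_fixture():
    """A plus-strand single-exon gene whose CDS covers a guide's PAM.

    Layout: 60 bp flank, ATG + codons + stop, 60 bp flank. The guide PAM's
    GG completes a proline codon CCG -> mutable to CCA/CCT/CCC.
    """
    #              flank               CDS
    cds = "ATG" + "GCTACTCCGGATTCTGTTAAAGCAACTGCTGATTCTGTT" + "TAA"
    seq = ("TGCATGCATTGCATGCATTGCATGCATTGCATGCATTGCATGCATTGCATGCATTGCAT"
           + cds
           + "TGCATGCATTGCATGCATTGCATGCATTGCATGCATTGCATGCATTGCATGCATTGCAT")
    assert len(cds) % 3 == 0
    a = GenomeAssembly({"c": seq})
    iso = IsoformModel(
        isoform_id="t1", exons=((60, 60 + len(cds)),),
        cds=((60, 60 + len(cds)),), start_codon=60,
        stop_codon=60 + len(cds) - 3,
    )
    return a, iso, seq


class TestMutatePamSilent:
    def test_synonymous_pam_change_in_cds(self):
        a, iso, seq = _mutation_fixture()
        # CCG codon at genomic [66, 69); make the guide's PAM cover its GG:
        # plus-strand PAM at [66, 69) = "CGG" -> GG at 67, 68 inside codon
        # CCG (genomic [66,69)? codon boundaries are 60,63,66,69...) ->
        # codon [66, 69) is "CCG"? seq[66:69]
        pam_start = seq.find("CGG", 60)
        proto = seq[pam_start - 20 : pam_start]
        guide = make_guide(proto, "CGG", "+", pam_start)
        arm = HomologyArm(seq[30:130], "c", 30, 130, "left")
        mutated, report = mutate_pam_silent(arm, guide, iso, "+")
        assert report.strategy == "pam-synonymous"
        (sub,) = report.substitutions
        assert sub.amino_acid is not None
        # the PAM no longer matches NGG
        new_pam = mutated.seq[pam_start - 30 : pam_start + 3 - 30]
        assert new_pam[1:] != "GG"
        # translation unchanged over the arm's CDS overlap
        orig_cds = seq[60 : 60 + 45]
        new_cds = mutated.seq[60 - 30 : 60 - 30 + 45]
        assert Seq(orig_cds).translate() == Seq(new_cds).translate()
        assert orig_cds != new_cds

    def test_noncoding_pam_direct_substitution(self):
        """A PAM entirely in the intergenic flank is disrupted by a direct
        G->T substitution with a non-coding note."""
        cds = "ATG" + "GCTACTCCGGATTCTGTTAAAGCAACTGCTGATTCTGTT" + "TAA"
        flank = "T" * 25 + "AGG" + "T" * 32  # PAM AGG at [25, 28)
        seq = flank + cds + "T" * 60
        iso = IsoformModel(
            isoform_id="t1", exons=((60, 60 + len(cds)),),
            cds=((60, 60 + len(cds)),), start_codon=60,
            stop_codon=60 + len(cds) - 3,
        )
        flank_pam = 25
        assert seq[flank_pam + 1 : flank_pam + 3] == "GG"
        guide = make_guide(seq[flank_pam - 20 : flank_pam],
                           seq[flank_pam : flank_pam + 3], "+", flank_pam)
        arm = HomologyArm(seq[0:60], "c", 0, 60, "left")
        mutated, report = mutate_pam_silent(arm, guide, iso, "+")
        assert report.strategy == "non-coding"
        (sub,) = report.substitutions
        assert sub.alt == "T" and sub.codon_before is None
        assert mutated.seq[sub.genomic_pos] == "T"

    def test_impossible_case_raises(self):
        """A PAM whose GG sits in single-codon amino acids (Met/Trp), with a
        seed that offers no synonymous change either, must hard-error."""
        cds = "ATG" + "TGGATGTGGATGTGGATGTGGATGTGGATG" + "TGGTAA"
        seq = "T" * 60 + cds + "T" * 60
        a = GenomeAssembly({"c": seq})
        iso = IsoformModel(
            isoform_id="t1", exons=((60, 60 + len(cds)),),
            cds=((60, 60 + len(cds)),), start_codon=60,
            stop_codon=60 + len(cds) - 3,
        )
        # PAM = the TGG codon at CDS offset 3: both G's are Trp bases
        pam_start = 63
        pam = seq[pam_start : pam_start + 3]
        assert pam == "TGG"
        guide = make_guide(seq[pam_start - 20 : pam_start], pam, "+", pam_start)
        # arm starts at the ATG so every in-arm seed position is coding
        arm = HomologyArm(seq[60:120], "c", 60, 120, "left")
        with pytest.raises(PamMutationError, match="pick another guide"):
            mutate_pam_silent(arm, guide, iso, "+")

    def test_seed_fallback_when_pam_unmutable(self):
        """GG locked in Trp codons but a seed with synonymous options falls
        back to >=1 silent seed change."""
        cds = "ATG" + "GCTACTCCGGATTCTGTTAAAGCA" + "TGGTGG" + "GCTTAA"
        seq = "T" * 60 + cds + "T" * 60
        a = GenomeAssembly({"c": seq})
        iso = IsoformModel(
            isoform_id="t1", exons=((60, 60 + len(cds)),),
            cds=((60, 60 + len(cds)),), start_codon=60,
            stop_codon=60 + len(cds) - 3,
        )
        # PAM over the TGG TGG pair: pick pam_start so GG bases are the
        # Trp G's (positions 88..93 hold TGGTGG)
        tgg = 60 + 27
        pam_start = tgg + 3  # PAM = seq[tgg+3 : tgg+6] = "TGG"
        guide = make_guide(seq[pam_start - 20 : pam_start],
                           seq[pam_start : pam_start + 3], "+", pam_start)
        arm = HomologyArm(seq[40:140], "c", 40, 140, "left")
        mutated, report = mutate_pam_silent(arm, guide, iso, "+")
        assert report.strategy == "seed-synonymous"
        assert 1 <= len(report.substitutions) <= 2
        # guide no longer matches mutated arm exactly
        assert guide.protospacer not in mutated.seq
        # translation preserved
        orig = Seq(cds).translate()
        new = Seq(mutated.seq[60 - 40 : 60 - 40 + len(cds)]).translate()
        assert orig == new


class TestFloxAndFrame:
    @pytest.mark.parametrize("name", [
        "pHD-SspB-ExLK-EGFP-DsRed", "pHD-EGFP-ExLK-SspB-DsRed",
        "pHD-DsRed", "pHD-DsRed-attP",
    ])
    def test_flox_excision_arithmetic(self, name):
        vec = get_vector(name)
        amap = vec.to_map()
        floxed = simulate_flox(amap)
        (l1, l2) = sorted(vec.loxp_spans)
        assert len(floxed.sequence) == len(amap.sequence) - (l2[0] - l1[0])
        assert len(floxed.features_labelled("loxP")) == 1
        assert floxed.sequence.count(amap.sequence[l1[0]:l1[1]]) == 1

    def test_refloxing_errors(self):
        vec = get_vector("pHD-DsRed")
        floxed = simulate_flox(vec.to_map())
        with pytest.raises(FloxError, match="2 loxP"):
            simulate_flox(floxed)

    def test_inverted_loxp_rejected(self):
        vec = get_vector("pHD-DsRed")
        amap = vec.to_map()
        feats = []
        for f in amap.features:
            if f.label == "loxP" and not feats or f.label != "loxP":
                feats.append(f)
        flipped = []
        seen = 0
        for f in amap.features:
            if f.label == "loxP":
                seen += 1
                if seen == 2:
                    from dataclasses import replace
                    f = replace(f, strand=-f.strand)
            flipped.append(f)
        bad = AssemblyMap(amap.name, amap.sequence, amap.topology,
                          tuple(flipped), amap.provenance_notes)
        with pytest.raises(FloxError, match="inverted"):
            simulate_flox(bad)

    def test_frame_offset_arithmetic(self):
        """An insert of length != 0 mod 3 fails with the right offset."""
        # synthetic floxed-style map: 2 codons CDS + insert + CDS/stop
        cds_up = "ATGGCT"
        insert = "GGTGGCG"  # 7 bp -> offset 1
        cds_down = "GATTCTTAA"
        seq = "TT" + cds_up + insert + cds_down + "TT"
        feats = (
            MapFeature(2, 8, 1, "CDS", "t1 CDS", (("isoform", "t1"),)),
            MapFeature(8, 15, 1, "misc_feature", "cassette",
                       (("inserted", "vector"),)),
            MapFeature(15, 24, 1, "CDS", "t1 CDS", (("isoform", "t1"),)),
        )
        amap = AssemblyMap("m", seq, "linear", feats)
        report = validate_frame(amap)
        assert not report.passes
        assert report.frame_offset == 1
        good = AssemblyMap(
            "m", seq[:8] + "GGTGGCGGA" + seq[8 + 7:], "linear",
            (feats[0],
             MapFeature(8, 17, 1, "misc_feature", "cassette",
                        (("inserted", "vector"),)),
             MapFeature(17, 26, 1, "CDS", "t1 CDS", (("isoform", "t1"),))),
        )
        ok = validate_frame(good)
        assert ok.passes and ok.inserted_length == 9 and ok.frame_offset == 0

    def test_junction_peptide_matches_independent_translation(self):
        """Junction peptide equals Biopython translation of the fused CDS."""
        cds_up = "ATGGCTAAAACT"
        insert = "GGTGGCGGATCA"  # 12 bp, stop-free in frame
        cds_down = "GATTCTGTTTAA"
        seq = "AA" + cds_up + insert + cds_down + "AA"
        feats = (
            MapFeature(2, 14, 1, "CDS", "t1 CDS", (("isoform", "t1"),)),
            MapFeature(14, 26, 1, "misc_feature", "cassette",
                       (("inserted", "vector"),)),
            MapFeature(26, 38, 1, "CDS", "t1 CDS", (("isoform", "t1"),)),
        )
        report = validate_frame(AssemblyMap("m", seq, "linear", feats))
        fused = cds_up + insert + cds_down
        assert report.passes
        assert report.junction_peptide == str(Seq(fused).translate())[:-1] + "*"


class TestGuideOligos:
    def test_g_start_protospacer_overhang_rule(self):
        g = make_guide("GACGATCGATCGATCGATCA", "AGG", "+", 100)
        fwd, rev, _ = design_guide_oligos(g, get_vector("pU6-BbsI-chiRNA"))
        assert fwd == "CTTCGACGATCGATCGATCGATCA"
        assert rev == "AAAC" + revcomp("ACGATCGATCGATCGATCA") + "C"

    def test_non_g_start_keeps_full_spacer(self):
        g = make_guide("ACGATCGATCGATCGATCAT", "AGG", "+", 100)
        fwd, rev, _ = design_guide_oligos(g, get_vector("pU6-BbsI-chiRNA"))
        assert fwd == "CTTCG" + "ACGATCGATCGATCGATCAT"
        assert rev == "AAAC" + revcomp("ACGATCGATCGATCGATCAT") + "C"

    def test_oligos_anneal(self):
        g = make_guide("TTCGATCGATCGATCGATCA", "AGG", "+", 100)
        fwd, rev, _ = design_guide_oligos(g, get_vector("pU6-BbsI-chiRNA"))
        assert revcomp(rev[4:]) == fwd[4:]

    def test_golden_gate_roundtrip(self):
        g = make_guide("GACGATCGATCGATCGATCA", "AGG", "+", 100)
        vec = get_vector("pU6-BbsI-chiRNA")
        _, _, amap = design_guide_oligos(g, vec)
        assert amap.topology == "circular"
        assert "GAAGAC" not in amap.sequence and "GTCTTC" not in amap.sequence
        assert amap.sequence.count(g.protospacer) == 1
        (promoter,) = [f for f in amap.features if f.type == "promoter"
                       and "U6" in f.label]
        (spacer,) = amap.features_labelled("protospacer")
        assert promoter.end <= spacer.start
        assert amap.sequence[spacer.start : spacer.end] == g.protospacer

    def test_vector_without_bbsi_rejected(self):
        g = make_guide("GACGATCGATCGATCGATCA", "AGG", "+", 100)
        vec = get_vector("pHD-DsRed")
        with pytest.raises(VectorError, match="BbsI"):
            design_guide_oligos(g, template_from_map(vec.to_map(), kind="guide"))


def _pick_guide_in_arm(assembly, gene, iso, terminus, arm_length=1000):
    """A guide whose full target lies inside one homology arm (so the
    silent-mutation path is exercised), plus the insertion point."""
    if terminus == "N":
        anchor = iso.start_codon
        b = iso.start_codon + 3 if gene.strand == "+" else iso.start_codon - 2
    else:
        anchor = iso.stop_codon
        b = iso.stop_codon if gene.strand == "+" else iso.stop_codon + 1
    for s in scan_guides(assembly, gene.contig, anchor, 120):
        gs, ge = (s.pam_start - 20, s.pam_start + 3) if s.strand == "+" \
            else (s.pam_start - 2, s.pam_start + 21)
        if b - arm_length <= gs and ge <= b or b <= gs and ge <= b + arm_length:
            return s, b
    raise AssertionError("no in-arm guide found")


class TestTaggingBuild:
    def test_length_identity_and_locus_identity(self, assembly, genes):
        gene = genes["g1"]
        iso = gene.isoforms[0]
        guide = scan_guides(assembly, gene.contig, iso.start_codon, 25)[0]
        vec = get_vector("pHD-SspB-ExLK-EGFP-DsRed")
        gv = get_vector("pU6-BbsI-chiRNA")
        res = build_tagging_maps(assembly, gene, iso, "N", guide, vec, gv)
        assert len(res.edited_map.sequence) == (
            len(res.locus_map.sequence) + len(vec.insert_seq)
        )
        lo = int(res.locus_map.provenance_notes[0].split(":")[1].split("-")[0])
        hi = lo + len(res.locus_map.sequence)
        assert res.locus_map.sequence == assembly.sequences[gene.contig][lo:hi]

    def test_in_arm_guide_triggers_silent_mutation(self, assembly, genes):
        gene = genes["g3"]
        iso = gene.isoforms[0]
        guide, b = _pick_guide_in_arm(assembly, gene, iso, "N")
        vec = get_vector("pHD-SspB-ExLK-mCherry-DsRed")
        gv = get_vector("pU6-BbsI-chiRNA")
        res = build_tagging_maps(assembly, gene, iso, "N", guide, vec, gv)
        (report,) = res.mutation_reports
        assert report.strategy != "not-needed"
        assert len(report.substitutions) >= 1

    def test_minus_strand_gene_insert_is_reverse_complemented(
        self, assembly, genes
    ):
        minus = next(g for g in genes.values() if g.strand == "-")
        iso = minus.isoforms[0]
        guide = scan_guides(assembly, minus.contig, iso.start_codon, 25)[0]
        vec = get_vector("pHD-SspB-ExLK-EGFP-DsRed")
        gv = get_vector("pU6-BbsI-chiRNA")
        res = build_tagging_maps(assembly, minus, iso, "N", guide, vec, gv)
        assert revcomp(vec.insert_seq) in res.edited_map.sequence
        assert res.frame_report is not None and res.frame_report.passes

    def test_wrong_vector_terminus_rejected(self, assembly, genes):
        gene = genes["g1"]
        iso = gene.isoforms[0]
        guide = scan_guides(assembly, gene.contig, iso.start_codon, 25)[0]
        with pytest.raises(DesignError, match="does not match"):
            build_tagging_maps(
                assembly, gene, iso, "N", guide,
                get_vector("pHD-EGFP-ExLK-SspB-DsRed"),
                get_vector("pU6-BbsI-chiRNA"),
            )


class TestDeletionBuild:
    def _guides(self, assembly, gene, iso):
        a = scan_guides(assembly, gene.contig, iso.start_codon, 25)[0]
        b = scan_guides(assembly, gene.contig, iso.stop_codon, 25)[0]
        return (a, b) if a.cut_pos < b.cut_pos else (b, a)

    def test_length_identity(self, assembly, genes):
        gene = genes["g1"]
        iso = gene.isoforms[0]
        gn, gc = self._guides(assembly, gene, iso)
        vec = get_vector("pHD-DsRed-attP")
        res = build_deletion_maps(
            assembly, gene, iso, gn, gc, vec, get_vector("pU6-BbsI-chiRNA"))
        expected = (
            len(res.locus_map.sequence) - (gc.cut_pos - gn.cut_pos)
            + len(vec.insert_seq)
        )
        assert len(res.edited_map.sequence) == expected

    def test_deletion_span_annotated(self, assembly, genes):
        gene = genes["g1"]
        iso = gene.isoforms[0]
        gn, gc = self._guides(assembly, gene, iso)
        res = build_deletion_maps(
            assembly, gene, iso, gn, gc, get_vector("pHD-DsRed"),
            get_vector("pU6-BbsI-chiRNA"))
        (feat,) = res.edited_map.features_labelled(f"deletion of {gene.gene_id}")
        note = feat.get("note")
        assert str(gn.cut_pos) in note and str(gc.cut_pos) in note

    def test_equal_cuts_rejected(self, assembly, genes):
        gene = genes["g1"]
        iso = gene.isoforms[0]
        g = scan_guides(assembly, gene.contig, iso.start_codon, 25)[0]
        with pytest.raises(DesignError, match="cutN < cutC"):
            build_deletion_maps(
                assembly, gene, iso, g, g, get_vector("pHD-DsRed"),
                get_vector("pU6-BbsI-chiRNA"))


class TestGenBankRoundTrip:
    def test_design_outputs_roundtrip(self, assembly, genes, tmp_path):
        gene = genes["g1"]
        iso = gene.isoforms[0]
        guide = scan_guides(assembly, gene.contig, iso.start_codon, 25)[0]
        res = build_tagging_maps(
            assembly, gene, iso, "N", guide,
            get_vector("pHD-SspB-ExLK-EGFP-DsRed"),
            get_vector("pU6-BbsI-chiRNA"))
        for amap in (res.guide_map, res.locus_map, res.edited_map,
                     res.donor_map):
            path = tmp_path / "m.gb"
            write_genbank(amap, path)
            back = read_genbank(path)
            assert back.sequence == amap.sequence
            assert back.topology == amap.topology
            got = sorted((f.start, f.end, f.strand, f.label)
                         for f in back.features)
            want = sorted((f.start, f.end, f.strand, f.label)
                          for f in amap.features)
            assert got == want

    def test_custom_vector_file_parses_to_template(self, tmp_path):
        vec = get_vector("pHD-SspB-ExLK-EGFP-DsRed")
        path = tmp_path / "custom.gb"
        write_genbank(vec.to_map(), path)
        tpl = template_from_map(read_genbank(path))
        assert tpl.kind == "tagging_N"
        assert tpl.left_arm_slot is not None and tpl.right_arm_slot is not None
        assert tpl.insert_seq == vec.insert_seq


class TestSpacerWithBbsiMotif:
    def test_spacer_carrying_bbsi_motif_builds_with_warning(self):
        g = make_guide("TTAGTCTTCTATCGATCGAT", "TGG", "+", 100)
        assert "GTCTTC" in g.protospacer
        fwd, rev, amap = design_guide_oligos(g, get_vector("pU6-BbsI-chiRNA"))
        assert amap.sequence.count(g.protospacer) == 1
        assert any("BbsI motif" in n for n in amap.provenance_notes)
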