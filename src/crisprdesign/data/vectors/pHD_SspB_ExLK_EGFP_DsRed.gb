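LOCUS       pHD_SspB_ExLK_EGFP_DsRed 3271 bp    DNA     circular SYN 01-JAN-1980
DEFINITION  pHD-SspB-ExLK-EGFP-DsRed.
ACCESSION   pHD_SspB_ExLK_EGFP_DsRed
VERSION     pHD_SspB_ExLK_EGFP_DsRed
KEYWORDS    .
SOURCE      .
  ORGANISM  .
            .
COMMENT     SYNTHETIC STAND-IN: backbone, ORFs, promoters and linkers are
            deterministic placeholder sequences with correct feature topology;
            only LoxP, the sgRNA scaffold and restriction-site motifs are
            canonical. Substitute a real vector GenBank file for wet-lab
            cloning.
FEATURES             Location/Qualifiers
     source          1..3271
                     /label="pHD-SspB-ExLK-EGFP-DsRed"
                     /note="SYNTHETIC STAND-IN: backbone, ORFs, promoters and
                     linkers are deterministic placeholder sequences with
                     correct feature topology; only LoxP, the sgRNA scaffold and
                     restriction-site motifs are canonical. Substitute a real
                     vector GenBank file for wet-lab cloning."
                     /vector_kind="tagging_N"
     rep_origin      1..300
                     /label="rep_origin (synthetic)"
     CDS             301..786
                     /label="AmpR (synthetic)"
     misc_feature    901..906
                     /label="EcoRI site"
     misc_feature    907..914
                     /label="NotI site"
     misc_feature    914^915
                     /label="HA_left_slot"
     CDS             915..1265
                     /label="SspB(R73Q)"
     CDS             1266..1307
                     /label="ExLK linker"
     CDS             1308..2027
                     /label="EGFP"
     misc_feature    2028..2036
                     /label="PmeI junction"
     misc_feature    915..2036
                     /label="cassette"
                     /frame_offset="0"
     protein_bind    2037..2070
                     /label="loxP"
     promoter        2071..2220
                     /label="3xP3 promoter"
     CDS             2221..2901
                     /label="DsRed"
     terminator      2902..3021
                     /label="marker terminator"
     protein_bind    3022..3055
                     /label="loxP"
     misc_feature    3056..3057
                     /label="frame_spacer"
     misc_feature    3057^3058
                     /label="HA_right_slot"
     misc_feature    3058..3065
                     /label="AscI site"
     misc_feature    3066..3071
                     /label="XhoI site"
ORIGIN
        1 taaacttccc acaacccgca aggcctagac tactggatcc caagcatgcc cgtcactccg
       61 ttttcagtct caggctggtg tctacattcg gtttggacat atcttaccgc tgcgtttttt
      121 tgaagaccct aacttacagt ctgccagcag cttcgcaagt ggtcttgtat tgcgaatgtg
      181 gatgtgattc tacgattgtt tcacaaggcg gcgttcatgc cctcgatccg aatgcattgt
      241 cgtgtgagct aagggctgaa agttagtacc gatagggagc tcttacacgc tgccgtccaa
      301 atggaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      361 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      421 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      481 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      541 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      601 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      661 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      721 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      781 atctaataat gactggagta gatgcaccgt tggataacct ccgaggccgc cgtagaacta
      841 atttccttac ttcggagctg ccccatctat cgaacggcca aactgaatag tgccgccaag
      901 gaattcgcgg ccgcgctgat gctactactg ctgatgctac tactgctgat gctactactg
      961 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     1021 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     1081 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     1141 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     1201 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     1261 ctgatggtgg cggaggttct acgcgtggtg gcggaggttc tcatatgtgg ggctggctcc
     1321 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1381 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1441 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1501 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1561 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1621 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1681 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1741 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1801 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1861 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1921 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctctgg ggctggctcc
     1981 tctggggctg gctcctctgg ggctggctcc tctggggctg gctcctcggt ttaaacataa
     2041 cttcgtataa tgtatgctat acgaagttat ggtacacaga cgttgcgctg ggtggtgaga
     2101 tttgcgttcc tcatcgaggg accgatgatc tgaaagtcac acatctaggc tgccattaac
     2161 tctcgtgcga gagatgaccc gccctcgggc gaatatgtcg aatctaaggg acttttcgat
     2221 atgcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2281 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2341 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2401 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2461 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2521 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2581 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2641 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2701 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2761 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2821 tggcgtttcc gttggtggcg tttccgttgg tggcgtttcc gttggtggcg tttccgttgg
     2881 tggcgtttcc gttggtggta aggtttctgt catggtaaag gtcaaacccc gaattaccag
     2941 cagctcatat cttccacgca ttgcggctac cctctccact caagcacaca gttcgacatt
     3001 gcacttaacc catacggatc aataacttcg tataatgtat gctatacgaa gttatccggc
     3061 gcgccctcga gtaatgactg gagtagatgc accgttggat aacctccgag gccgccgtag
     3121 aactaatttc cttacttcgg agctgcccca tctatcgaac ggccaaactg aatagtgccg
     3181 ccaagtagag gcccgttggt tccccctcca aatactgcgg cactcctttt tgactgtcgc
     3241 caatttatga gcgactatta agtcgatgct c
//
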