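LOCUS       pHD_mCherry_ExLK_SspB_DsRed 3277 bp    DNA     circular SYN 01-JAN-1980
DEFINITION  pHD-mCherry-ExLK-SspB-DsRed.
ACCESSION   pHD_mCherry_ExLK_SspB_DsRed
VERSION     pHD_mCherry_ExLK_SspB_DsRed
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
     source          1..3277
                     /label="pHD-mCherry-ExLK-SspB-DsRed"
                     /note="SYNTHETIC STAND-IN: backbone, ORFs, promoters and
                     linkers are deterministic placeholder sequences with
                     correct feature topology; only LoxP, the sgRNA scaffold and
                     restriction-site motifs are canonical. Substitute a real
                     vector GenBank file for wet-lab cloning."
                     /vector_kind="tagging_C"
     rep_origin      1..300
                     /label="rep_origin (synthetic)"
     CDS             301..786
                     /label="AmpR (synthetic)"
     misc_feature    901..908
                     /label="SrfI site"
     misc_feature    909..914
                     /label="EcoRI site"
     misc_feature    915..922
                     /label="NotI site"
     misc_feature    922^923
                     /label="HA_left_slot"
     protein_bind    923..956
                     /label="loxP"
     promoter        957..1106
                     /label="3xP3 promoter"
     CDS             1107..1787
                     /label="DsRed"
     terminator      1788..1907
                     /label="marker terminator"
     protein_bind    1908..1941
                     /label="loxP"
     misc_feature    1942..1943
                     /label="frame_spacer"
     misc_feature    1944..1952
                     /label="NotI junction"
     CDS             1953..2672
                     /label="mCherry"
     CDS             2673..2714
                     /label="ExLK linker"
     CDS             2715..3065
                     /label="SspB(R73Q)"
     misc_feature    1944..3065
                     /label="cassette"
                     /frame_offset="0"
     misc_feature    3065^3066
                     /label="HA_right_slot"
     misc_feature    3066..3071
                     /label="BglII site"
     misc_feature    3072..3077
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
      901 gcccgggcga attcgcggcc gcataacttc gtataatgta tgctatacga agttatggta
      961 cacagacgtt gcgctgggtg gtgagatttg cgttcctcat cgagggaccg atgatctgaa
     1021 agtcacacat ctaggctgcc attaactctc gtgcgagaga tgacccgccc tcgggcgaat
     1081 atgtcgaatc taagggactt ttcgatatgc gtttccgttg gtggcgtttc cgttggtggc
     1141 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1201 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1261 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1321 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1381 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1441 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1501 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1561 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1621 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1681 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggcgtttc cgttggtggc
     1741 gtttccgttg gtggcgtttc cgttggtggc gtttccgttg gtggtaaggt ttctgtcatg
     1801 gtaaaggtca aaccccgaat taccagcagc tcatatcttc cacgcattgc ggctaccctc
     1861 tccactcaag cacacagttc gacattgcac ttaacccata cggatcaata acttcgtata
     1921 atgtatgcta tacgaagtta tccgcggccg caggcctcgg ccgtcgtggc ctcggccgtc
     1981 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2041 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2101 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2161 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2221 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2281 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2341 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2401 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2461 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2521 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2581 gtggcctcgg ccgtcgtggc ctcggccgtc gtggcctcgg ccgtcgtggc ctcggccgtc
     2641 gtggcctcgg ccgtcgtggc ctcggccgtc gtggtggcgg aggttctacg cgtggtggcg
     2701 gaggttctca tatggctgat gctactactg ctgatgctac tactgctgat gctactactg
     2761 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     2821 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     2881 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     2941 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     3001 ctgatgctac tactgctgat gctactactg ctgatgctac tactgctgat gctactactg
     3061 ctgatagatc tctcgagtaa tgactggagt agatgcaccg ttggataacc tccgaggccg
     3121 ccgtagaact aatttcctta cttcggagct gccccatcta tcgaacggcc aaactgaata
     3181 gtgccgccaa gtagaggccc gttggttccc cctccaaata ctgcggcact cctttttgac
     3241 tgtcgccaat ttatgagcga ctattaagtc gatgctc
//
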