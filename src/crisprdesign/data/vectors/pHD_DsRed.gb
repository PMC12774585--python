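LOCUS       pHD_DsRed               2147 bp    DNA     circular SYN 01-JAN-1980
DEFINITION  pHD-DsRed.
ACCESSION   pHD_DsRed
VERSION     pHD_DsRed
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
     source          1..2147
                     /label="pHD-DsRed"
                     /note="SYNTHETIC STAND-IN: backbone, ORFs, promoters and
                     linkers are deterministic placeholder sequences with
                     correct feature topology; only LoxP, the sgRNA scaffold and
                     restriction-site motifs are canonical. Substitute a real
                     vector GenBank file for wet-lab cloning."
                     /vector_kind="deletion"
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
     protein_bind    915..948
                     /label="loxP"
     promoter        949..1098
                     /label="3xP3 promoter"
     CDS             1099..1779
                     /label="DsRed"
     terminator      1780..1899
                     /label="marker terminator"
     protein_bind    1900..1933
                     /label="loxP"
     misc_feature    915..1933
                     /label="cassette"
                     /frame_offset="0"
     misc_feature    1933^1934
                     /label="HA_right_slot"
     misc_feature    1934..1941
                     /label="AscI site"
     misc_feature    1942..1947
                     /label="XhoI site"
ORIGIN
        1 cgctgtaacg aaacccgttg gccgtgatcg cctagcaatg tagactgaat cgctacaatg
       61 tataaaaagg tacgccgcca cgcggtttct gacgcattat ggactatagc gcattgtcta
      121 gtctcacaac ccttcagtag ccttctgcga aaataacctg tacagcttag gctcggactc
      181 gactctgtac caatcgccga tctgcatggc gatcactaac gcctatacgt cagcagctat
      241 gagaccggcc cataaaggat tggacgatcc tcacctacgg attcttccga ggggggatag
      301 atggaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      361 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      421 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      481 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      541 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      601 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      661 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      721 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      781 atctaacggg aagggaacgc gatgtttagt cagacaggaa cagcattcat ccggcgcccg
      841 agagtatcag gaatttaggg ctctcagagg ggaactggta tcaccagggt tgtagccttt
      901 gaattcgcgg ccgcataact tcgtataatg tatgctatac gaagttatgg tacacagacg
      961 ttgcgctggg tggtgagatt tgcgttcctc atcgagggac cgatgatctg aaagtcacac
     1021 atctaggctg ccattaactc tcgtgcgaga gatgacccgc cctcgggcga atatgtcgaa
     1081 tctaagggac ttttcgatat gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1141 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1201 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1261 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1321 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1381 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1441 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1501 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1561 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1621 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1681 tggtggcgtt tccgttggtg gcgtttccgt tggtggcgtt tccgttggtg gcgtttccgt
     1741 tggtggcgtt tccgttggtg gcgtttccgt tggtggtaag gtttctgtca tggtaaaggt
     1801 caaaccccga attaccagca gctcatatct tccacgcatt gcggctaccc tctccactca
     1861 agcacacagt tcgacattgc acttaaccca tacggatcaa taacttcgta taatgtatgc
     1921 tatacgaagt tatggcgcgc cctcgagcgg gaagggaacg cgatgtttag tcagacagga
     1981 acagcattca tccggcgccc gagagtatca ggaatttagg gctctcagag gggaactggt
     2041 atcaccaggg ttgtagcctt tgggggaacg ctgcggcgga cttgtgttga tacggattga
     2101 ttgttagtgg gaggggattc gataaacccg tgccacatta gggaatt
//
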