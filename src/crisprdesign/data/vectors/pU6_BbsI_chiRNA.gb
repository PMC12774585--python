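LOCUS       pU6_BbsI_chiRNA         1183 bp    DNA     circular SYN 01-JAN-1980
DEFINITION  pU6-BbsI-chiRNA.
ACCESSION   pU6_BbsI_chiRNA
VERSION     pU6_BbsI_chiRNA
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
     source          1..1183
                     /label="pU6-BbsI-chiRNA"
                     /note="SYNTHETIC STAND-IN: backbone, ORFs, promoters and
                     linkers are deterministic placeholder sequences with
                     correct feature topology; only LoxP, the sgRNA scaffold and
                     restriction-site motifs are canonical. Substitute a real
                     vector GenBank file for wet-lab cloning."
                     /vector_kind="guide"
     rep_origin      1..300
                     /label="rep_origin (synthetic)"
     CDS             301..486
                     /label="AmpR (synthetic)"
     promoter        601..850
                     /label="U6 promoter (synthetic)"
     misc_feature    complement(857..862)
                     /label="BbsI site"
     misc_feature    863..892
                     /label="stuffer"
     misc_feature    893..898
                     /label="BbsI site"
     misc_RNA        901..976
                     /label="sgRNA scaffold"
     terminator      977..983
                     /label="U6 terminator"
ORIGIN
        1 gatcatatca tttgcagacc caagcatttg gtgcgatcct caacggcgtc ggtgaactcg
       61 tgactcgcac ccacctttgg gttattatca gatgtcggat acggtaaagc gatagatgtg
      121 caggctcagg gggttagctc catcggtcac tcccctcgac atgtaaatca ccgatcgtaa
      181 ctaaaaaacc taattctccg tcgagccgaa taaaactcca tctggtccga tccagtaggt
      241 tggcgtccga gaagctctcg tgacgccccc acattaggcg acgttagcgt ccatgctaat
      301 atggaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      361 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      421 atcgaatctg aaatcatcga atctgaaatc atcgaatctg aaatcatcga atctgaaatc
      481 atctaagcta gatcgctagg gtatcgctca tggcgctagc ctgggacagc gaaaaacatc
      541 agcacatgag ccgtaggggc ccggggacaa tcaaccgtca cttaccaacc ttaagcatgc
      601 tttgcggatg aaagatgagt taccgtttcc ccattatctc atgtcctgaa ggataggtag
      661 ttgaacggcg gattcttatg ccgaaacgcg tgtagtccct ctagttccgc tgtccgtcca
      721 ccgttatgct gaagtgctga cgtgattaat gagatgttac cgtacccaat acccttatcc
      781 aggtgtctac cccataggcc gtatcatacc ccgccatgac ggtgaagtat tcatattcag
      841 cacctgctgc cttcaagtct tcgctagatc gctagggtat cgctcatggc gcgaagacaa
      901 gttttagagc tagaaatagc aagttaaaat aaggctagtc cgttatcaac ttgaaaaagt
      961 ggcaccgagt cggtgctttt ttttcatacc ttttcacttc tagggggcaa ggtacgccga
     1021 ttagctcgca gctatttatg ggttgcatag gagaatcctc cttctaattc agcgctctca
     1081 gtgaaaaacc agcgccccca cgcacagaag tgtattattg gttcctatgc taagaccagg
     1141 ttgctgagcc cactcgccgc tgcagatctt atgatacaca ctt
//
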