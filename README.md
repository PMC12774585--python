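# crisprdesign

Offline, scriptable design of CRISPR/Cas9 **gene-deletion** and
**endogenous-tagging** (knock-in) experiments for annotated genomes.

Fluorescent or optogenetic tagging of a gene at its own locus by
homology-directed repair (HDR) requires a surprising amount of coordinated
bookkeeping: a Cas9 cut site close to the start or stop codon, an efficiency
and off-target assessment of each candidate guide, PCR and sequencing primers
to verify the locus before cloning, ~1 kb homology arms flanking the
insertion point, a donor plasmid whose PAM has been silently mutated so the
repaired allele is not re-cut, and — when the screening marker is removed by
Cre/LoxP recombination — a reading-frame check across the residual 34-bp LoxP
scar that ends up as a peptide linker inside the fusion protein.
`crisprdesign` performs all of these steps locally and deterministically, and
emits three annotated GenBank cloning maps per design (guide vector, unaltered
locus, edited locus + donor plasmid) that open in any plasmid editor.

It is aimed at fly (or any small-genome) molecular biologists planning
SpCas9 knock-in/knock-out constructs, and at tool builders who want an
auditable, fully offline reference pipeline: every nontrivial step
(PAM scanning, Hamming off-target counting, golden-gate assembly, Cre
excision, silent mutation) is implemented against brute-force oracles in the
test suite.

## The method in brief

* **Guide search.** All 20-nt protospacers adjacent to an NGG PAM on either
  strand whose blunt cut (3 bp 5′ of the PAM, between protospacer bases 17
  and 18) falls within a window around the start codon (N-terminal tagging)
  or stop codon (C-terminal tagging / deletion ends).
* **Ranking.** Efficiency is a plug-in 20×4 position-weight matrix score
  `S = Σᵢ w[i, bᵢ]`; off-targets are exact Hamming-distance counts
  (0–3 mismatches) over all NGG-adjacent 20-mers genome-wide. Sites with an
  exact off-target are demoted to the end and flagged, never hidden.
* **Primers.** Amplification primers 1000–1200 bp and sequencing primers
  400–600 bp from the cut on both sides, filtered on nearest-neighbor Tm
  (SantaLucia–Hicks 2004 unified parameters, 50 mM Na⁺), GC, homopolymer
  runs and 3′ self-complementarity.
* **Donor assembly.** 1000-bp homology arms anchored at the insertion point;
  cassette inserted immediately after the ATG (N) or before the stop codon
  (C), so no genomic base is lost; two-cut deletions satisfy
  `len(edited) = len(locus) − (cut_C − cut_N) + len(cassette)` exactly.
* **Silent PAM disruption.** Priority: synonymous codon change in the PAM's
  GG → direct substitution if the PAM is non-coding → synonymous (or
  non-coding) changes in the 10-nt seed; a hard error if nothing silent
  disrupts the target.
* **Cre/LoxP simulation.** The 3xP3-DsRed screening marker between two LoxP
  sites is excised in silico; the retained LoxP + 2-bp frame spacer form an
  in-frame 12-codon linker, and the validator translates from the ATG
  through the cassette into the downstream CDS to prove it.

Seven built-in vector templates are included (four tagging vectors carrying
SspB(R73Q)::EGFP/mCherry fusion cassettes for the iLID optogenetic system,
two deletion vectors, and a U6/BbsI guide-expression vector). Their
backbones are clearly-labelled synthetic stand-ins with correct feature
topology; drop in your own GenBank files for real cloning (features
`HA_left_slot`, `HA_right_slot`, `cassette`, optional `loxP` pair).

## Worked example

Generate a seeded 60-kb synthetic genome with five genes, rank guides around
the start codon of `g1`, and design an N-terminal EGFP tag:

```bash
crisprdesign fixtures --out fix --seed 42 --n-genes 5
crisprdesign guides --genome fix/genome.fa --annotation fix/genes.gff3 --gene g1 | head -3
crisprdesign tag --genome fix/genome.fa --annotation fix/genes.gff3 \
    --gene g1 --terminus N --fluorophore EGFP --out design
```

The guide table (tab-separated) ranks by efficiency, then off-target burden,
then cut-to-anchor distance:

```
protospacer           pam  strand  contig  pam_start  cut_pos  anchor_distance  efficiency  ot0  ot1  ot2  ot3
TGCTATGCGCATAACAGCTA  CGG  +       chr1    6358       6355     13               0.2300      0    0    0    0
GCGCATAACAGCTACGGCTT  GGG  +       chr1    6364       6361     19               0.1200      0    0    0    0
```

`ot0..ot3` are genome-wide match counts at 0–3 mismatches (0 exact matches =
the site is unique). The `tag` run writes `g1_guides.gb`, `g1_locus.gb`,
`g1_edited.gb` (genomic edit + circular donor) and `g1_report.txt`:

```
tagging g1 at the N-terminus with pHD-SspB-ExLK-EGFP-DsRed
guide: TGCTATGCGCATAACAGCTA CGG (+) cut at 6355, efficiency 0.2300, off-targets {0: 0, 1: 0, 2: 0, 3: 0}
guide 1 forward oligo: CTTCGTGCTATGCGCATAACAGCTA
guide 1 reverse oligo: AAACTAGCTGTTATGCGCATAGCAC
PAM disruption strategy: not-needed (guide target spans the insertion point; cassette insertion itself disrupts it)
flox frame check: PASS (insert 1158 bp, in frame)
```

The oligos are ready for BbsI golden-gate cloning into the U6 guide vector
(the leading `CTTCG`/`AAAC…C` bases are the annealed overhangs); the frame
check proves that after Cre excision the 1158-bp residual insert (cassette +
LoxP scar + spacer) is a multiple of three with no premature stop, and the
report prints the fusion-junction peptide including the LoxP-derived linker
(`…ITSYNVCYTKLS…`). Here the chosen guide's target spans the insertion
point, so the cassette itself destroys it and no PAM mutation is needed;
when the target survives inside a homology arm, the report instead lists
each silent substitution with its codon and amino acid.

## Library use

```python
from crisprdesign import (parse_fasta, parse_gff3, scan_guides,
                          count_offtargets, rank_guides, get_vector,
                          build_tagging_maps, write_genbank)

assembly = parse_fasta("fix/genome.fa")
gene = parse_gff3("fix/genes.gff3", assembly)[0]
iso = gene.isoforms[0]
sites = [s.with_offtargets(count_offtargets(s, assembly))
         for s in scan_guides(assembly, gene.contig, iso.start_codon, 20)]
best = rank_guides(sites)[0]
result = build_tagging_maps(assembly, gene, iso, "N", best,
                            get_vector("pHD-SspB-ExLK-EGFP-DsRed"),
                            get_vector("pU6-BbsI-chiRNA"))
write_genbank([result.edited_map, result.donor_map], "edited.gb")
```

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.
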