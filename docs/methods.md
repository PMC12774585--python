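# Methods

This note documents the models, conventions and numerical choices behind
`crisprdesign`, what the synthetic data generator does and does not emulate,
and the package's known limitations.

## Coordinate conventions

All internal coordinates are 0-based, half-open, plus-strand genomic.
GFF3's 1-based inclusive coordinates are converted once, in the parser, and
strand is applied only at sequence extraction. `start_codon` is the genomic
position of the first CDS base in transcription order (for a minus-strand
gene, the numerically largest CDS base); `stop_codon` is the first base of
the stop codon in transcription order.

## Guide model

A target site is a 20-nt protospacer 5′ of an NGG PAM. `pam_start` is the
plus-strand coordinate of the PAM's first base read in the site's own 5′→3′
direction; SpCas9's blunt cut lies between protospacer bases 17 and 18
(3 bp 5′ of the PAM), and the stored `cut_pos` is the coordinate of base 18
— `pam_start − 3` on '+' and `pam_start + 3` on '−'. This symmetric
convention keeps the cut inside the protospacer interval on both strands
and makes window arithmetic strand-free.

The default search window is ±20 bp of cut position around the anchor codon
(configurable, `guide_window`). Tagging requires the cut near the insertion
point to suppress re-cutting after repair; cuts farther than
`max_cut_distance` (default 10 bp) from the insertion point are warned
about, not rejected. Sites containing N are discarded; N bases are legal in
the genome but invalidate designs. Guides overlapping the anchor codon are
kept and flagged, since the inserted cassette will disrupt them anyway.

### Efficiency score

Efficiency is a sum of per-position weights from a 20×4 matrix,
`S = Σᵢ w[i, baseᵢ]`, higher is better. The shipped default matrix is a
**synthetic stand-in** (its provenance header says so): it encodes only
broad qualitative trends (G favoured at position 20, purines near the PAM,
T disfavoured in the seed) to make ranking deterministic and auditable. It
is not a trained model, its absolute scale is arbitrary, and nothing in the
package or tests depends on its specific values — any whitespace-delimited
20×4 table with an `A C G T` header can be substituted.

### Off-target model

Off-targets are counted exactly: for each mismatch count m in 0..3, the
number of 20-mers adjacent to an NGG PAM anywhere in the genome (both
strands) at Hamming distance exactly m from the protospacer, excluding the
site's own locus. No bulges, no position-dependent mismatch weighting, no
cleavage-likelihood score (CFD/MIT), no NAG PAMs. Hamming counting was
chosen because it is oracle-testable — the test suite compares the
vectorized scanner against an exhaustive double-loop on hundreds of random
genomes — and because downstream use is a ranking tie-break, not a safety
guarantee. N in the PAM position excludes the window; N inside a window
never matches any protospacer base.

### Ranking

Deterministic composite key: sites with any exact off-target (ot0 > 0) go
to the end of the list, flagged; within each group, efficiency descending,
then Σ(ot1..ot3) ascending, then |cut − anchor| ascending, stable
thereafter. Demotion-not-removal is deliberate: the tool surfaces risky
guides rather than silently censoring them, and the user confirms the final
pick (`--pick-guide`).

## Primer model

Four search windows are measured **from the cut position to the primer's 5′
end**: amplification primers 1000–1200 bp up/downstream, sequencing primers
400–600 bp up/downstream. The measuring point (cut vs codon vs arm edge) is
a documented package convention; distances themselves are the pipeline's
fixed design parameters. Amplification primers must pair (forward '+'
upstream, reverse '−' downstream) so the product spans both homology arms;
sequencing primers are single oligos reading inward.

Defaults: length 18–27 nt, Tm 57–63 °C, GC 30–70 %, homopolymer ≤ 4,
3′ self-complementarity ≤ 3 bp, product-size optimum 2200 bp, top 5
returned. These are conventional PCR defaults, all configurable. Tm uses
Biopython's nearest-neighbor implementation with the SantaLucia & Hicks
(2004) unified parameter table, 50 mM Na⁺, the SantaLucia (1998)
0.368·(N−1)·ln[Na⁺] entropy correction and 25 nM strand concentrations; the
Wallace rule (2·AT + 4·GC) is available for quick estimates. The test suite
re-derives NN temperatures from an independently coded parameter table to
0.01 °C. Hairpin/dimer thermodynamics (ΔG) are out of scope; the 3′
self-complementarity filter is a crude proxy.

Pairs are ranked by |Tm_f − Tm_r| ascending, then |product − optimum|, then
coordinates — byte-identical output for identical input.

## Donor construction

Homology arms default to 1000 bp, anchored at the insertion point: left arm
ends at it, right arm starts at it, both exact plus-strand genomic
substrings. Arms running off a contig are shortened with a warning. For
N-terminal tagging the cassette is inserted immediately after the start
codon's ATG; for C-terminal immediately before the stop codon — both
preserve every genomic base, giving the exact length identity
`len(edited) = len(locus) + len(insert)`. Two-cut deletions replace
`[cut_N, cut_C)` with the marker cassette:
`len(edited) = len(locus) − (cut_C − cut_N) + len(insert)`.

For minus-strand genes the cassette is reverse-complemented into the genome
and the donor arms are flipped into transcript orientation, so the fusion
reads correctly off the gene's own strand.

### Silent PAM disruption

A donor still matching the guide at 0 mismatches will be re-cut after
repair. The builder checks the assembled donor (arms + insert) for an exact
protospacer+NGG match — this also catches the subtle case where the PAM
straddles the insertion junction and the insert's first base reconstitutes
the NGG. If a match survives, mutation priority is:

1. a synonymous single-base codon change that removes a PAM G (alphabetical
   first alternative codon — deterministic);
2. if the PAM base is outside annotated CDS, a direct G→T change (guide
   strand);
3. otherwise, changes in the PAM-proximal 10-nt seed, closest-to-PAM first:
   synonymous codon changes inside CDS, free transversions outside CDS, two
   preferred, one accepted.

If nothing silent disrupts the target, the design fails loudly with advice
to pick another guide. Every substitution is reported with position,
plus-strand before/after base, codon and amino acid, and annotated as a
`variation` feature in the edited map. The invariant — translated mutated
arm CDS equals translated original arm CDS — is enforced by tests over all
built-in vectors and fixture genes.

### LoxP, frame spacer, and the flox simulation

Cre excises everything between the starts of two identical, same-orientation
LoxP sites, leaving one 34-bp LoxP — used deliberately as a peptide linker
in the final fusion. The canonical LoxP is stop-free only when read from
its first base (registers 1 and 2 hit a TAA), and 34 ≢ 0 (mod 3). The
templates therefore absorb the register themselves: each fusion cassette is
a multiple of 3 (so the LoxP is reached at a codon boundary) and a 2-bp
`CC` frame spacer follows the second LoxP, making the retained scar a clean
12-codon linker (…ITSYNVCYTKLS). `simulate_flox` refuses zero, one, >2 or
inverted LoxP sites (Cre inversion is out of scope); `validate_frame` then
translates from the isoform ATG through the residual insert into the
downstream CDS and passes only if the insert length is ≡ 0 (mod 3), there
is no premature stop, and the natural stop terminates the fusion. Frame
validation is a hard gate in `build_tagging_maps` for any floxable vector.

### Guide oligos and golden-gate simulation

Guide oligos follow the standard U6/BbsI convention: forward
`CTTCG + spacer` (a protospacer already starting with G contributes 19
bases, otherwise the overhang's G supplies the U6-preferred 5′ G), reverse
`AAAC + revcomp(spacer) + C`. BbsI digestion (GAAGAC, 2/6, 4-nt 5′
overhangs) is simulated explicitly: both vector sites must face the stuffer,
overhang complementarity is verified, and assembly fails if a vector site
survives. A BbsI motif inside the spacer itself is recorded as a cloning
caveat (one-pot re-digestion risk) rather than an error, since it is a
property of the genome, not of the assembly.

## Built-in vectors

Seven templates ship as GenBank data files: four tagging vectors
(SspB(R73Q)–linker–FP and FP–linker–SspB(R73Q), FP ∈ {EGFP, mCherry}) with
a LoxP-flanked 3xP3-DsRed screening marker, two deletion vectors (marker
only, ± attP landing site retained after floxing), and the U6/BbsI guide
vector. Backbones, ORFs, promoters and the extended flexible linker are
**deterministic synthetic stand-ins** built from repeating codon pools —
stop-free, BbsI-free, with restriction-site annotations (EcoRI/NotI/NdeI/
PmeI/MluI/AscI/XhoI/SrfI/BglII) placed consistently with the cloning slots
they serve. Only LoxP, the sgRNA scaffold and the restriction motifs are
canonical sequences. A test regenerates the files from the generator and
asserts byte identity; template invariants (identical LoxP pair, marker
between them, cassette stop-free in its register, scar codon-aligned) are
checked at load time. The internal rotation keeps every feature clear of
the circular origin. Real experiments should substitute real vector files;
the loader accepts any GenBank with the documented slot labels.

## Synthetic mini-genome generator

`make_mini_genome` emulates just enough of an annotated genome to exercise
every pipeline branch deterministically: uniform random intergenic sequence;
genes on both strands with ATG…stop CDSs of random non-stop codons, split
across a configurable number of exons by GT…AG introns (codon-split exon
boundaries included; terminal exons keep ≥ 6 bp so anchor codons are never
split); a JSON truth table of all coordinates and CDS strings; and
optionally planted exact duplicates of a guide locus as off-target positive
controls. Defaults: 1 contig × 60 kb, 5 genes, 2 exons, 300 codons, 2.8-kb
flanks (room for 1-kb arms and 1.2-kb primer windows). Identical specs are
byte-identical.

What it does **not** emulate: realistic base composition or repeats,
UTRs/alternative isoforms, nested or overlapping genes, regulatory
elements, sequencing errors or polymorphism. Passing tests therefore
demonstrate the pipeline's coordinate arithmetic, search completeness and
construct soundness — not guide-efficiency realism or off-target risk in a
repeat-rich real genome, where Hamming counts on a true assembly (and an
experimentally trained efficiency model) should inform the final choice.

## Determinism

Every ranking has a total, documented tie-break; GenBank output pins the
LOCUS date; the generator derives everything from its seed. Two identical
CLI invocations produce byte-identical maps and reports, and the test suite
and acceptance script both verify this.

## Problem sizes in the checks

The verification suite runs the scanner oracle on ~200 random sequences of
150–2000 bp, the off-target oracle on genomes up to 10 kb, and full donor
builds for every built-in vector across five fixture genes on the 60-kb
default genome — sizes at which the brute-force oracles stay exact and the
whole suite completes in seconds while covering every code path the larger
problems would.

## Known limitations

- Off-target counting is exact-match Hamming only; no bulges, no NAG, no
  cleavage scoring.
- The efficiency matrix is a labelled placeholder, not a predictive model.
- No primer secondary-structure thermodynamics; no primer3 integration.
- No scarless strategies (PBac excision, marker-excision gRNAs), no Cre
  inversion, no phiC31/attP integration simulation beyond carrying the
  annotation.
- Single-isoform designs: the cassette is placed for the chosen isoform;
  effects on other isoforms of the same gene are not analysed.
- Vector stand-ins are topological, not clonable, sequences.
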