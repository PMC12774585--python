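# builtin-synthetic position-weight efficiency matrix
# Provenance: SYNTHETIC stand-in written for this package. It is NOT a
# published or machine-learned guide-efficiency model; it encodes only
# broadly reported qualitative trends (purine preference near the PAM,
# G favoured at position 20, T disfavoured in the seed) so that ranking
# is deterministic and auditable. Substitute your own 20x4 table to use a
# real model; only the scoring contract (sum of per-position weights) is
# fixed.
# Rows = protospacer positions 1..20 (PAM-distal to PAM-proximal).
A	C	G	T
0.02	0.00	0.05	-0.02
0.01	0.01	0.03	-0.01
0.02	-0.01	0.04	-0.02
0.00	0.02	0.03	-0.01
0.03	-0.02	0.04	-0.03
0.02	0.00	0.05	-0.02
0.01	0.02	0.03	-0.02
0.03	-0.01	0.04	-0.04
0.02	0.01	0.05	-0.03
0.04	-0.02	0.06	-0.04
0.03	0.00	0.06	-0.05
0.05	-0.03	0.07	-0.05
0.04	-0.02	0.08	-0.06
0.06	-0.03	0.08	-0.07
0.05	-0.04	0.09	-0.08
0.07	-0.04	0.10	-0.09
0.08	-0.05	0.12	-0.10
0.09	-0.05	0.13	-0.11
0.10	-0.06	0.15	-0.12
0.12	-0.08	0.20	-0.14
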