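# element mass table v1 — symbol, monoisotopic (Da), average (Da)
# sources: CODATA/IUPAC standard atomic weights, most-abundant-isotope masses
H	1.0078250319	1.00794
C	12.0	12.0107
N	14.0030740052	14.0067
O	15.9949146221	15.9994
P	30.97376151	30.973762
S	31.97207069	32.065
Cl	34.96885271	35.453
Na	22.98976928	22.98976928
K	38.9637064864	39.0983
Fe	55.9349375	55.845
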