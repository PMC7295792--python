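# monoisotopic atomic masses (Da), CODATA/NIST; table version 1
H	1.00782503207
C	12.0
N	14.0030740048
O	15.9949146196
P	30.97376163
S	31.97207100
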