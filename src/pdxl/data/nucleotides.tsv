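# deoxynucleotide elemental compositions; table version 1
# base	dNMP (5'-monophosphate free acid)	deoxynucleoside	nucleobase
A	C10H14N5O6P	C10H13N5O3	C5H5N5
C	C9H14N3O7P	C9H13N3O4	C4H5N3O
G	C10H14N5O7P	C10H13N5O4	C5H5N5O
T	C10H15N2O8P	C10H14N2O5	C5H6N2O2
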