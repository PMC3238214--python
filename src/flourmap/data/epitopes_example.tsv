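# EXAMPLE epitope library (synthetic fixture).
# Motif sequences are transcribed from the celiac-disease literature and are
# external to the spot catalogue shipped with this package; verify against the
# primary immunology sources before drawing any biological conclusion.
name	sequence	source
33-mer	LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF	alpha-gliadin immunodominant 33-mer (literature)
p31-43	LGQQQPFPPQQPY	alpha-gliadin innate-immunity peptide (literature)
glia-alpha-9	PFPQPQLPY	T-cell stimulatory epitope (literature)
glia-alpha-2	PQPQLPYPQ	T-cell stimulatory epitope (literature)
glia-alpha-20	FRPQQPYPQ	T-cell stimulatory epitope (literature)
glia-alpha	QGSFQPSQQ	T-cell stimulatory epitope (literature)
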