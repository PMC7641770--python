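# Built-in candidate table for PDE cleavage-product identification.
# Average molecular masses (Da) computed from the package's IUPAC standard
# atomic weights; formula column is documentation.  Extend freely: the
# identify functions accept any (name, average_mass) table.
name	average_mass	formula
5'-AMP	347.22	C10H14N5O7P
5'-CMP	323.20	C9H14N3O8P
5'-UMP	324.18	C9H13N2O9P
5'-GMP	363.22	C10H14N5O8P
adenosine	267.24	C10H13N5O4
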