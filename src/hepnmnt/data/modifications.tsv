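# Built-in modification adducts for intact-protein mass-shift stoichiometry.
# Residue masses: mass the adduct adds to the protein (free molecule minus
# one water for condensation adducts).  avg from IUPAC standard atomic
# weights, mono from principal-isotope masses.
name	residue_mass_avg	residue_mass_mono	formula
AMP	329.21	329.0525	C10H12N5O6P
phospho	79.98	79.9663	HPO3
acetyl	42.04	42.0106	C2H2O
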