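# Seven-residue hydrophobic pocket on the Plk1 polo-box domain.
# Val415, Leu478, Phe482 form the bottom; Tyr417, Tyr421, Tyr481, Tyr485
# the sides.  Gates: Tyr417, Tyr481 (primary), Phe482.  The closed-state
# reference is the chi1 of the Tyr481 rotamer stacked onto Phe482.
# closed_chi1_ref -65.0
# closed_halfwidth 40.0
A 415 VAL bottom no
A 417 TYR side yes
A 421 TYR side no
A 478 LEU bottom no
A 481 TYR side primary
A 482 PHE bottom yes
A 485 TYR side no
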