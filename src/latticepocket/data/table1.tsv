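# Thermal-shift (delta-Tm, degrees C) and ITC results for phosphopeptides
# against the wild-type Plk1 polo-box domain and the pocket-ablating
# Y417A/Y421A double mutant.  pS/pT mark the phosphorylated residue.
peptide	tm_shift_wt	tm_shift_mut	kd_um	dh_kcal
FMPPPMSpSM	2.0	2.0	515	-18.7
FDPPLHSpTA	14.4	10.1	0.25	-17.6
ADPPLHSpTA	10.5	10.7	1.32	-15.7
DPPLHSpTA	9.7	10.1	2.14	-17.1
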