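# Synthetic example motif table (motif_id <TAB> classification <TAB> IUPAC DNA motif).
# Stand-in for a protein-domain scan: each row maps a short degenerate
# nucleotide motif to the TE superfamily it diagnoses. These motifs are
# synthetic examples for demonstrations and tests, not real domain models;
# supply your own table for real screens.
tc1_ddd_box	DNA/Tc1-Mariner	GAYGCNGAYGGNATGWS
hat_dimer	DNA/hAT	TGGCARGTNMGNAARCC
harbinger_tnp	DNA/PIF-Harbinger	ATGGCNGCNAARYTNGG
cr1_rt_core	LINE/CR1	TAYGCNGAYGAYATGYT
l1_en_core	LINE/L1	GCNCAYTGYGARGCNTT
gypsy_int_core	LTR/Gypsy	CAYYTNGGNATHACNAA
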