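name	e0_mv	n	reference_state	source
H2	-414.0	2	pH 7, 25 C, unit activity	standard tabulation
AH2QDS	-184.0	2	pH 7, standard state	anthrahydroquinone-2,6-disulfonate; literature estimate
methanophenazine	-165.0	2	pH 7	membrane electron carrier; literature estimate
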