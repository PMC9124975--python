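name	phase	charge	dgf0_kj_mol	source
FeS2	solid	0	-160.2	pyrite; printed study value
pyrrhotite	solid	0	-136.0	Fe0.86S; printed study value
mackinawite	solid	0	-89.2	FeS; printed study value
HS-	aqueous	-1	12.05	bisulfide; standard geochemical compilation (supplemented)
H+	proton-reference	1	0.0	convention (pH activity scale)
H2(aq)	aqueous	0	17.7	dissolved hydrogen, 1 M reference state; standard compilation (supplemented)
H2(g)	gas	0	0.0	hydrogen gas, 1 bar reference state; convention
H2O	water	0	-237.18	liquid water; standard compilation
e-	electron	-1	0.0	electron pseudo-species for half-reactions; convention
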