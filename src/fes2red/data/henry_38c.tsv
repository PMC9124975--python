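species	kh_m_per_bar	temperature_k	source
h2	7.92e-4	311.15	calibrated so 2.5 bar pure H2 gives 1.98e-3 M aqueous; within literature range
h2s	0.0866	311.15	hydrogen sulfide at 38 C (0.0877 M/atm); reproduces 30.5 uM <-> 3.53 umol closed-bottle balance
ch4	1.1e-3	311.15	methane at 38 C; literature solubility adjusted from 25 C
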