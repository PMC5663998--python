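# Synthetic MS2 peak list, precursor m/z 913.9 [M-2H]2-, second-eluting isomer
# (48 min): LacdiNAc-type core-fucosylated N-glycan,
# (Gal)1(GalNAc)1(GlcNAc)2(Fuc)1 + (Man)3(GlcNAc)2.
# Transcribed from the printed diagnostic values (B ion 405.1, F ion 465.1)
# plus backbone B/Y ions at one-decimal precision; intensities are nominal.
364.1	20.0
405.1	60.0
424.1	12.0
465.1	35.0
526.2	18.0
567.2	22.0
571.2	10.0
729.3	26.0
1260.5	12.0
1301.5	14.0
1422.5	18.0
1463.6	16.0
1625.6	28.0
1666.6	15.0
1682.6	24.0
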