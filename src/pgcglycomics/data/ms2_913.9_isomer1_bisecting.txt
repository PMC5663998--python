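# Synthetic MS2 peak list, precursor m/z 913.9 [M-2H]2-, first-eluting isomer
# (38.5 min): bisecting-GlcNAc-type core-fucosylated N-glycan,
# (Gal)1(GlcNAc)3(Fuc)1 + (Man)3(GlcNAc)2.
# Transcribed from the printed diagnostic values (D-221 at 508.1, D at 729.3)
# plus backbone B/Y ions at one-decimal precision; intensities are nominal.
364.1	28.0
368.2	12.0
424.1	18.0
508.1	55.0
526.2	22.0
571.2	15.0
729.3	40.0
1256.4	10.0
1301.5	14.0
1463.6	20.0
1625.6	30.0
1666.6	16.0
1682.6	25.0
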