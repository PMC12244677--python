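# SYNTHETIC innervation-length side table (m), deltoid heads collapsed.
# Least-squares construction jointly consistent with the packaged afferent/efferent
# delays at conduction velocities 56.8 / 29.1 m/s (armloop.fixtures.synthetic_innervation_lengths).
muscle,length_m
Delt,0.154459
Pec,0.239519
Bi,0.351148
Tri,0.353314
Bra,0.329762
Brd,0.386088
PT,0.398587
ECR,0.49637
ECU,0.501359
FCR,0.45383
FCU,0.601151
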