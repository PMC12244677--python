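# Excess-of-central-delay values (milliseconds), deltoid heads collapsed.
# Rows = source muscle, columns = target muscle; blank cell = not measured.
# Homonymous cells are blank by definition (no excess over the 1 ms synaptic delay).
source,Delt,Pec,Bi,Tri,Bra,Brd,PT,ECR,ECU,FCR,FCU
Delt,,1.5,0.067,0,,0.1,,,,,
Pec,1.5,,0,0,,,,,,,
Bi,0,0,,1.22,,,1,,,1.5,1.5
Tri,0,0,1.22,,,,,1.5,,1.5,1.5
Bra,,,,,,,,,,,
Brd,,,0.95,1.5,,,1,0,,1.05,
PT,,,0,1.2,,-0.07,,0,,,
ECR,,,1.2,0,,0,0,,,0.817,
ECU,,,1.2,0,,,,,,0.95,1
FCR,,,0,1.2,,0.86,,0.983,1,,
FCU,,,,,,,,,,0,
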