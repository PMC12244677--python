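# Relative muscle-spindle feedback gain matrix G (unitless).
# Rows = source muscle, columns = target muscle; blank cell = no literature value (missing, not zero).
source,Delt Ant,Delt Lat,Delt Post,Pec,Bi,Tri,Bra,Brd,PT,ECR,ECU,FCR,FCU
Delt Ant,0.23,,,,0.36,,,,,,,,
Delt Lat,0.23,,,,0.31,,,,,,,,
Delt Post,0.23,,0.50,-0.067,-0.003,0.013,,,,,,,
Pec,,,-0.052,0.50,0.035,0.002,,,,,,,
Bi,0.23,,0.008,0.024,0.50,-0.19,,,-0.50,0,,-0.22,-0.29
Tri,0.41,,0.005,0.005,-0.30,0.50,,,,-0.28,,-0.25,-0.31
Bra,,,,,-0.36,-0.23,,,,,,,
Brd,,,0.091,,-0.42,-0.29,,,-0.55,0.39,,-0.24,
PT,,,,,0.43,-0.2,,0.31,,0.46,,,
ECR,0.38,,0.091,,-0.058,0.19,,,0.47,1.24,0,-0.47,
ECU,,,0.091,,-0.058,0.19,,,,1.24,0.96,,
FCR,0,,,,0.32,-0.25,,-0.15,,-0.46,,1.2,0.59
FCU,0,,0.41,,0.19,-0.15,,,,,,1.2,2.6
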