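# SYNTHETIC marker coordinates. Published QTLs are defined by flanking marker
# names; assembly positions for these markers are not part of the shipped
# inputs, so this demonstration map places them at invented coordinates.
marker	chromosome	position
RZ14	chr01	40500000
R117	chr01	43200000
RM7332	chr03	1200000
RM545	chr03	2400000
RG104	chr03	1900000
RZ329	chr03	3100000
C136	chr03	29500000
R1618	chr03	31200000
RM72	chr08	9800000
RM331	chr08	11400000
RM5353	chr08	25400000
RM3480	chr08	26900000
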