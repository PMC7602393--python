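# SYNTHETIC demonstration QTL set: drought-tolerance QTLs flanked by the
# markers in synthetic_marker_map.tsv (whose coordinates are invented).
qtl_id	chromosome	left_marker	right_marker	source
qDT1.1	chr01	RZ14	R117	Q-TARO
qDT3.1	chr03	RM7332	RM545	Q-TARO
qDT3.2	chr03	RG104	RZ329	Q-TARO
qDT3.3	chr03	C136	R1618	Q-TARO
qDT8.1	chr08	RM72	RM331	Q-TARO
qDT8.2	chr08	RM5353	RM3480	Q-TARO
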