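ligand_id,3B66,3G0W,3V49,4HLW,2PNU
3B66,-12.2,-8.5,-8.9,NA,-10.9
3G0W,-10.8,-11.2,-10.6,-8.4,-10.0
3V49,-10.5,NA,-12.2,NA,-9.7
4HLW,-8.8,NA,-9.4,-11.3,-10.0
2PNU,NA,NA,NA,NA,-14.2
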