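ligand_id,class
3B66,agonist
3G0W,agonist
3V49,agonist
4HLW,agonist
2PNU,agonist
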