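id,smiles
D1,CCO
D2,CC(=O)Nc1ccc(O)cc1
D3,ClC(Cl)Cl
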