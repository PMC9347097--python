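drug_id,protein_id,value
D1,P1,5.2
D1,P2,6.1
D2,P1,7.4
D2,P2,5.9
D3,P1,8.0
D3,P2,6.6
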