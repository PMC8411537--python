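((Dvir:0.5,Dmoj:0.5):0.5,(Dwil:0.85,((Dper:0.15,Dpse:0.15):0.5,(Dana:0.45,((Dere:0.15,Dyak:0.15):0.15,(Dmel:0.2,(Dsec:0.08,Dmau:0.08):0.12):0.1):0.15):0.2):0.2):0.15);
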