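condition,MAP,P_GC,Q_A,SNGFR
Sham,119.7,46.9,125.8,38.8
Sham + NF449,122.8,56.2,215.6,53.7
AngII,162.8,55.8,76.1,21.3
AngII + NF449,171.6,56.6,213.1,48.8
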