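element,rfd_ug_per_kg_day,sf_per_mg_kg_day,mac_ug_per_kg
As,0.3,1.5,200
Cd,1.0,6.1,100
Pb,3.5,0.0085,200
Cu,40.0,,10000
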