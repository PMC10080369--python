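,accident,assault,legal_intervention,self_harm,unknown
accident,21,4,0,0,3
assault,3,261,5,2,29
legal_intervention,1,1,1,0,0
self_harm,1,3,2,12,1
unknown,1,16,0,0,14
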