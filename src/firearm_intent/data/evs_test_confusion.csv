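,accident,assault,legal_intervention,self_harm,unknown
accident,31,14,0,2,3
assault,12,178,8,0,6
legal_intervention,0,2,3,0,0
self_harm,3,5,0,33,1
unknown,1,1,0,0,1
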