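population,M183*,SM001*,PF6794*,PF6789,CTS12227,Z5009,Other
Western Sahara,0,16,0,0,0,4,6
Morocco,3,14,0,3,19,48,53
Algeria (Oran),0,4,0,3,11,4,29
Algeria (Reguibates),0,23,1,0,0,8,7
Tunisia,0,8,0,9,5,11,58
Libya,2,11,1,3,3,5,51
Egypt,0,3,0,0,0,2,95
Near East,0,3,0,1,0,2,368
Iberian Peninsula,5,9,1,2,2,3,1062
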