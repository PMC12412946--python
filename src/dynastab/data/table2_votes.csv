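source,target,neg,zero,pos
P04040,P00441,0,1,99
P00441,P04040,1,98,1
P04040,P32119,0,100,0
P32119,P04040,0,0,100
P04040,P30046,100,0,0
P30046,P04040,2,98,0
Q06830,P04040,100,0,0
P04040,P13716,0,0,100
P13716,P04040,1,1,98
Q06830,P00441,100,0,0
P00441,Q13228,0,0,100
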