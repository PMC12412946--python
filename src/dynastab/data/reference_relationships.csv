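source,target,effect,category,n_refs
P04040,P00441,unknown,Regulation/Expression,34
P00441,P04040,unknown,Regulation,14
P04040,P32119,negative,Expression,2
P32119,P04040,unknown,Direct Regulation,5
P04040,P30046,unknown,Regulation,3
P30046,P04040,unknown,Regulation,3
Q06830,P04040,negative,Regulation,1
P04040,P13716,positive,Regulation,1
P13716,P04040,positive,Regulation,1
Q06830,P00441,unknown,Modification,1
P00441,Q13228,positive,Expression,1
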