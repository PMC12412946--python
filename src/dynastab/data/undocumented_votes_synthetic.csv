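source,target,neg,zero,pos
U01A,U01B,0,0,100
U02A,U02B,0,0,100
U03A,U03B,0,0,100
U04A,U04B,0,0,100
U05A,U05B,0,0,100
U06A,U06B,0,0,100
U07A,U07B,0,0,100
U08A,U08B,0,0,100
U09A,U09B,0,0,100
U10A,U10B,0,0,100
U11A,U11B,0,0,100
U12A,U12B,0,0,100
U13A,U13B,100,0,0
U14A,U14B,100,0,0
U15A,U15B,100,0,0
U16A,U16B,100,0,0
U17A,U17B,100,0,0
U18A,U18B,5,25,70
U19A,U19B,70,25,5
U20A,U20B,5,25,70
U21A,U21B,70,25,5
U22A,U22B,5,25,70
U23A,U23B,70,25,5
U24A,U24B,5,25,70
U25A,U25B,0,100,0
U26A,U26B,0,100,0
U27A,U27B,0,100,0
U28A,U28B,10,80,10
U29A,U29B,10,80,10
U30A,U30B,10,80,10
U31A,U31B,10,80,10
U32A,U32B,10,80,10
U33A,U33B,10,80,10
U34A,U34B,10,80,10
U35A,U35B,10,80,10
U36A,U36B,10,80,10
U37A,U37B,10,80,10
U38A,U38B,10,80,10
U39A,U39B,10,80,10
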