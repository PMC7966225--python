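side,total,count
cleft,0,6
cleft,1,3
cleft,2,0
cleft,3,3
cleft,4,1
cleft,5,2
cleft,6,0
cleft,7,0
cleft,8,2
cleft,9,1
cleft,10,0
cleft,11,2
cleft,12,1
noncleft,0,0
noncleft,1,0
noncleft,2,0
noncleft,3,0
noncleft,4,0
noncleft,5,0
noncleft,6,0
noncleft,7,0
noncleft,8,0
noncleft,9,0
noncleft,10,3
noncleft,11,9
noncleft,12,9
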