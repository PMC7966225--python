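side,level_mm,score,count
cleft,3,0,13
cleft,3,1,3
cleft,3,2,3
cleft,3,3,2
cleft,5,0,9
cleft,5,1,5
cleft,5,2,3
cleft,5,3,4
cleft,7,0,7
cleft,7,1,7
cleft,7,2,2
cleft,7,3,5
cleft,9,0,10
cleft,9,1,4
cleft,9,2,4
cleft,9,3,3
noncleft,3,0,0
noncleft,3,1,0
noncleft,3,2,10
noncleft,3,3,11
noncleft,5,0,0
noncleft,5,1,0
noncleft,5,2,4
noncleft,5,3,17
noncleft,7,0,0
noncleft,7,1,0
noncleft,7,2,1
noncleft,7,3,20
noncleft,9,0,0
noncleft,9,1,0
noncleft,9,2,0
noncleft,9,3,21
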