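animal,region,denom_marker,num_marker,positive,denominator
mouse1,CnF,Vglut2,D1,18,55
mouse2,CnF,Vglut2,D1,58,171
mouse3,CnF,Vglut2,D1,36,138
mouse1,CnF,Vglut2,D2,20,58
mouse2,CnF,Vglut2,D2,47,140
mouse3,CnF,Vglut2,D2,23,48
mouse4,CnF,Vglut2,D2,15,32
mouse1,PPN,Vglut2,D1,31,126
mouse2,PPN,Vglut2,D1,54,135
mouse3,PPN,Vglut2,D1,58,160
mouse1,PPN,Vglut2,D2,58,120
mouse2,PPN,Vglut2,D2,25,45
mouse3,PPN,Vglut2,D2,12,25
mouse1,CnF,D2,D1,2,22
mouse2,CnF,D2,D1,5,41
mouse3,CnF,D2,D1,2,27
mouse4,CnF,D2,D1,11,75
mouse1,PPN,D2,D1,1,12
mouse2,PPN,D2,D1,10,50
mouse3,PPN,D2,D1,1,33
mouse4,PPN,D2,D1,8,75
mouse1,CnF,D1,D2,2,8
mouse2,CnF,D1,D2,5,45
mouse3,CnF,D1,D2,2,10
mouse4,CnF,D1,D2,11,48
mouse1,PPN,D1,D2,1,8
mouse2,PPN,D1,D2,10,35
mouse3,PPN,D1,D2,1,15
mouse4,PPN,D1,D2,8,35
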