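animal,trial,attempt,success,duration_s,pre_strike
A,1,True,True,2.6,True
B,1,True,True,5.7,True
C,1,True,True,3.9,True
D,1,True,True,34.7,False
D,1,True,True,7.3,True
D,2,True,True,13.7,True
D,3,True,True,5.3,True
D,4,True,True,24.3,False
D,4,True,True,35.3,False
D,4,True,True,12.5,False
D,4,True,True,33.0,True
E,1,True,True,8.5,False
E,1,True,True,3.6,True
F,1,True,False,24.8,True
F,1,True,False,12.9,False
G,1,True,False,17.7,True
G,1,True,False,23.3,False
G,2,False,False,18.2,False
G,2,False,False,42.0,False
G,2,False,False,12.5,False
G,3,False,False,19.0,False
H,1,False,False,12.1,False
H,1,False,False,6.7,False
H,1,False,False,5.1,False
H,2,False,False,31.7,False
H,2,False,False,13.8,False
I,1,False,False,6.9,False
J,1,False,False,11.6,False
J,1,False,False,5.7,False
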