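19
glycine19 idealized template
C 2.395985 -0.610591 -1.606751
C 1.576691 -0.497905 -0.350896
O 1.830172 0.315670 0.532834
N 0.493301 -1.337282 -0.299456
C -0.407127 -1.368025 0.844668
C -1.480532 -0.272677 0.814743
O -2.652999 -0.504814 1.100587
N -1.002334 0.994654 0.553997
C -1.849949 2.150925 0.676950
H 2.202874 -1.553664 -2.125771
H 3.457456 -0.574733 -1.346647
H 2.149556 0.221294 -2.271504
H 0.188889 -1.801181 -1.145636
H 0.168079 -1.266395 1.770810
H -0.902321 -2.343817 0.834321
H 0.005493 1.123754 0.647204
H -1.982599 2.377722 1.738122
H -2.824856 1.955064 0.222497
H -1.365780 2.992002 0.175706
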