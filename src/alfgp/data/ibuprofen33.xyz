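33
ibuprofen33 idealized template
C -3.149593 -1.214996 -0.893794
C -3.078764 -0.856169 0.592729
C -4.491360 -0.815421 1.180853
C -2.376418 0.495460 0.828039
C -0.907848 0.489111 0.476385
C -0.444749 1.155041 -0.663957
C 0.913789 1.144646 -0.990818
C 1.839034 0.467613 -0.184309
C 1.372146 -0.195528 0.959945
C 0.013844 -0.184702 1.285989
C 3.310721 0.465988 -0.554871
C 3.823013 -0.944696 -0.853954
C 4.162400 1.119116 0.517752
O 4.714139 0.567903 1.457369
O 4.265787 2.456082 0.361588
H -3.665252 -0.436543 -1.466371
H -2.150044 -1.345888 -1.319915
H -3.691586 -2.155660 -1.039715
H -2.525696 -1.651384 1.108528
H -5.100445 -0.042383 0.699929
H -4.459558 -0.603463 2.254823
H -4.996942 -1.777628 1.046674
H -2.891169 1.286486 0.266855
H -2.464007 0.780422 1.885178
H -1.139968 1.686470 -1.309991
H 1.242098 1.673311 -1.883267
H 2.063335 -0.725310 1.613494
H -0.320307 -0.705952 2.180424
H 3.458623 1.048858 -1.474351
H 4.873888 -0.915174 -1.163079
H 3.761533 -1.600561 0.021694
H 3.244828 -1.408731 -1.660590
H 4.794530 2.743681 1.134857
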