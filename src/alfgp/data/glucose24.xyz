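24
glucose24 idealized template
O 2.093779 0.842830 0.643024
C 2.257203 0.243321 -0.635727
C 0.938720 -0.254713 -1.257582
O 0.053227 0.821980 -1.612403
C -0.764695 1.361633 -0.582512
O -0.022133 2.207792 0.291614
C -1.527388 0.284010 0.211374
O -2.186466 0.864050 1.350676
C -0.569114 -0.800459 0.702938
O -1.320970 -1.869906 1.308569
C 0.215432 -1.362851 -0.479097
O 1.105208 -2.392520 -0.047751
H 1.589384 1.668799 0.479154
H 2.966549 -0.582792 -0.526030
H 2.716333 0.993562 -1.288962
H 1.240635 -0.697779 -2.215925
H -1.498410 2.017043 -1.063322
H -0.399513 2.067268 1.184465
H -2.296373 -0.180324 -0.418466
H -2.923482 1.406898 1.012734
H 0.094652 -0.431711 1.491397
H -1.860182 -1.442478 2.003245
H -0.499757 -1.848362 -1.156613
H 0.597359 -2.915289 0.605201
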