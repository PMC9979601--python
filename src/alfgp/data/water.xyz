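3
water idealized template
O 0.007712 0.397740 0.000000
H 0.759468 -0.213670 0.000000
H -0.767180 -0.184070 0.000000
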