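rg_original,rg_linearized
25.4,23.58
28.5,26.35
32,29.99
36,33.07
40.3,37.35
45.2,43.15
50.8,49.45
57,55.05
64,62.05
71.8,69.60
80.6,76.10
90.5,85.10
101,96.80
114,109.80
128,124.00
144,140.00
161,153.00
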