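serial,serum_age,predicted_age,printed_relative_error
1,5.05,5.36,6.10
2,3.75,3.94,5.10
3,6.52,6.67,2.40
4,5.92,5.64,-4.80
5,4.46,4.68,5.00
6,4.18,4.11,-1.70
7,4.56,4.69,2.90
8,4.79,4.90,2.40
9,3.22,3.05,-5.20
10,3.29,3.22,-2.40
11,4.40,4.52,2.80
12,2.35,2.42,3.00
13,4.06,3.89,-4.00
14,4.88,5.02,2.90
15,2.80,2.89,3.30
16,4.22,4.21,-0.20
17,2.34,2.46,5.10
18,2.40,2.21,-7.60
19,3.12,3.19,2.30
20,3.85,3.66,-4.90
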