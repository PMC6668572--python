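trial_number,l2_multiplier,keep_prob
1,0.43498,84.61%
2,0.01698,83.74%
3,0.00085,75.27%
4,0.22378,28.34%
5,0.00771,38.11%
6,0.06408,97.57%
7,0.02045,64.27%
8,0.00294,66.68%
9,0.02925,66.28%
10,0.08087,80.31%
11,0.00011,98.59%
12,0.00018,0.23%
13,0.01049,69.53%
14,0.00726,58.78%
15,0.00225,89.91%
16,0.00364,31.68%
17,0.00139,55.35%
18,0.06780,46.09%
19,0.00546,43.48%
20,0.01878,53.98%
21,0.00603,80.00%
22,0.01834,77.79%
23,0.00476,73.39%
24,0.00408,55.14%
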