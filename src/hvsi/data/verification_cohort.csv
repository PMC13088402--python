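number,age,gender,anastomosis_type,vessel_bifurcation,flow_volume,resistance_index,flagged_by_cutoff,hvsi,matching_fv_hvsi,matching_vaivt_hvsi
1,73,Female,AVF,No,668,0.48,Yes,71,No,Yes
2,73,Male,AVF,Yes,207,0.73,Yes,61,Yes,Yes
3,81,Male,AVF,No,896,0.57,No,845,Yes,Yes
4,82,Female,AVF,No,866,0.41,No,675,Yes,Yes
5,57,Female,AVF,No,926,0.62,No,217,Yes,Yes
6,58,Male,AVF,No,715,0.59,No,486,Yes,Yes
7,79,Female,AVF,No,609,0.62,No,200,Yes,Yes
8,60,Female,AVF,No,1032,0.44,No,686,Yes,Yes
9,70,Male,AVF,No,1200,0.53,No,600,Yes,Yes
10,81,Female,AVF,No,469,0.49,No,298,Yes,Yes
11,58,Male,AVF,No,755,0.53,No,881,Yes,Yes
12,46,Male,AVF,Yes,1341,0.41,No,698,Yes,Yes
13,66,Female,AVF,No,924,0.47,No,498,Yes,Yes
14,67,Male,AVF,No,781,0.51,No,920,Yes,Yes
15,75,Male,AVF,No,983,0.54,No,575,Yes,Yes
16,69,Male,AVF,Yes,160,0.75,Yes,41,Yes,Yes
17,54,Male,AVF,No,1274,0.34,No,839,Yes,Yes
18,73,Male,AVF,No,405,0.59,No,299,Yes,Yes
19,81,Female,AVF,No,261,0.69,Yes,122,No,No
20,62,Male,AVF,No,3025,0.39,No,999,Yes,Yes
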