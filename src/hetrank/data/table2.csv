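case_id,pct_1plus,pct_2plus,pct_3plus,her2_status,printed_component_1,printed_component_2,printed_component_3,printed_score,printed_category,note
1,20,50,30,negative,5,25,30,60,intermediate,
2,0,40,60,positive,0,20,60,80,hyper-intense,dash entries for 1+ recorded as 0
3,5,55,40,positive,1.25,27.5,40,68.75,hyper-intense,
4,33,33,33,negative,8.25,16.5,33,57.75,intermediate,percentages sum to 99; remainder treated as grade 0
5,5,55,40,positive,1.25,27.5,40,68.75,hyper-intense,
6,30,40,30,negative,7.5,20,30,57.5,intermediate,
7,10,60,30,positive,2.5,30,30,62.5,intermediate,
8,10,20,70,positive,2.5,10,70,82.5,hyper-intense,
9,75,25,0,negative,18.75,12.5,0,31.25,hypo-intense,
10,10,40,50,positive,2.5,20,50,72.5,hyper-intense,
11,30,30,40,negative,7.5,15,40,62.5,intermediate,
12,10,20,70,negative,2.5,10,70,82.5,hyper-intense,
13,45,50,5,negative,11.25,25,5,41.25,intermediate,
14,80,20,0,negative,20,10,0,30,hypo-intense,
15,0,20,80,negative,0,10,80,90,hyper-intense,
16,0,0,100,positive,0,0,100,100,hyper-intense,
17,30,60,10,negative,7.5,30,10,47.5,intermediate,source table prints the accumulated score as 4705; the components sum to 47.5 and that arithmetic value is stored here
18,10,60,30,positive,2.5,30,30,62.5,intermediate,
19,0,25,75,positive,0,12.5,75,87.5,hyper-intense,
20,5,50,45,negative,1.25,25,45,71.25,hyper-intense,
21,25,65,10,negative,6.25,32.5,10,48.75,intermediate,
22,0,10,90,negative,0,5,90,95,hyper-intense,
23,10,60,30,positive,2.5,30,30,62.5,intermediate,
24,40,45,15,negative,10,22.5,15,47.5,intermediate,
25,30,30,40,negative,7.5,15,40,62.5,intermediate,
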