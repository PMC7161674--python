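patient_id,entry_diagnosis,age_band,etiology,days_from_event,cr_response,crsr_w1,ncs_w1,crsr_w2,ncs_w2,crsr_w3,ncs_w3,crsr_w4,ncs_w4,final_diagnosis
1,UWS,50–55,HEM,27,1,4,3,4,3,8,4,8,4,MCS
2,UWS,60–65,HEM,39,1,6,5,7,7,9,6,11,7,MCS
3,UWS,16–20,TBI,28,1,4,1,4,1,7,3,8,3,MCS
4,UWS,66–70,TBI,25,1,6,5,6,5,10,8,12,7,MCS
5,UWS,60–65,TBI,26,1,4,3,5,3,9,5,8,5,MCS
6,UWS,30–35,TBI,21,1,5,2,5,2,8,4,10,5,MCS
7,UWS,66–70,TBI,39,1,4,4,8,3,8,5,8,5,MCS
8,UWS,16–20,TBI,25,1,4,2,8,3,14,5,14,7,MCS
9,UWS,36–40,ANOX,21,1,4,3,6,2,4,3,6,4,UWS
10,UWS,66–70,HEM,23,0,4,4,7,3,4,3,7,5,UWS
11,UWS,40–45,HEM,55,0,4,1,4,1,4,1,4,1,UWS
12,UWS,46–50,HEM,32,0,4,1,3,4,3,3,5,4,UWS
13,UWS,56–60,HEM,24,0,5,3,4,3,5,3,5,3,UWS
14,UWS,56–60,HEM,35,0,4,3,4,3,4,3,6,3,UWS_LATE
15,UWS,56–60,HEM,39,0,3,1,5,3,5,3,6,3,UWS
16,UWS,66–70,HEM,58,0,5,3,5,3,6,3,6,3,UWS
17,UWS,60–65,HEM,34,0,5,3,6,3,5,3,4,4,UWS
18,UWS,56–60,TBI,30,0,5,1,5,4,4,3,5,4,UWS
19,UWS,46–50,TBI,23,0,2,1,7,5,5,3,5,5,UWS
20,UWS,60–65,TBI,33,0,6,3,6,3,6,3,6,3,UWS
21,UWS,56–60,TBI,36,0,5,2,5,2,5,2,7,5,UWS
22,UWS,20–25,TBI,27,0,5,2,6,2,6,4,6,4,UWS
23,UWS,20–25,TBI,27,0,4,3,6,4,6,3,5,3,UWS
24,UWS,26–30,TBI,28,0,6,3,5,4,5,4,7,4,UWS
25,UWS,26–30,TBI,23,0,6,5,6,5,7,6,7,5,UWS
26,UWS,20–25,TBI,21,0,5,3,6,3,7,4,7,4,UWS_LATE
27,UWS,66–70,ANOX,25,0,5,4,6,4,6,5,7,7,UWS
28,UWS,60–65,ANOX,23,0,5,1,5,2,4,2,4,2,UWS
29,UWS,26–30,ANOX,31,0,3,3,3,3,6,3,6,3,UWS
30,UWS,40–45,ANOX,37,0,4,1,5,2,6,2,5,3,UWS
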