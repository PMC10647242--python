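group,n_group,characteristic,level,count,percent
training,158,age,<60,70,44.3
training,158,age,>60,88,55.7
test,68,age,<60,22,32.4
test,68,age,>60,46,67.6
external,96,age,<60,29,30.2
external,96,age,>60,67,69.8
training,158,gender,female,99,62.7
test,68,gender,female,35,51.5
external,96,gender,female,57,59.4
training,158,smoking,smoker,35,22.2
test,68,smoking,smoker,23,33.8
external,96,smoking,smoker,21,21.9
training,158,ecog,0,49,31.0
training,158,ecog,1,91,57.6
training,158,ecog,2,11,7.0
training,158,ecog,>2,7,4.4
test,68,ecog,0,35,51.5
test,68,ecog,1,28,41.2
test,68,ecog,2,4,5.9
test,68,ecog,>2,1,1.5
external,96,ecog,0,4,4.2
external,96,ecog,1,65,67.7
external,96,ecog,2,10,10.4
training,158,histology,adeno,155,98.1
test,68,histology,adeno,65,95.6
external,96,histology,adeno,89,92.7
training,158,t_stage,1,19,12.0
training,158,t_stage,2,41,25.9
training,158,t_stage,3,27,17.1
training,158,t_stage,4,67,42.4
training,158,n_stage,0,45,28.5
training,158,n_stage,1,13,8.2
training,158,n_stage,2,40,25.3
training,158,n_stage,3,59,37.3
test,68,n_stage,0,14,20.6
test,68,n_stage,1,6,8.8
test,68,n_stage,2,22,32.4
test,68,n_stage,3,25,36.8
training,158,m_stage,0,6,3.8
training,158,stage,IIIB,14,8.9
training,158,stage,IVA,62,39.2
training,158,stage,IVB,82,51.9
training,158,egfr,ex19del,70,44.3
training,158,egfr,L858R,77,48.7
training,158,tki,gefitinib,29,18.4
training,158,tki,erlotinib,45,28.5
training,158,tki,afatinib,84,53.2
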