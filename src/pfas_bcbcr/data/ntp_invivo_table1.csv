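name,sex,liver_weight,relative_liver_weight,kidney_weight,relative_kidney_weight,decreased_hematocrit,decreased_cholesterol,decreased_t3,decreased_free_t4,decreased_total_t4,plasma_at_lowest_lel_ngml
PFBS,female,250,125,NA,62.6,NA,500,62.6,62.6,62.6,154.3
PFBS,male,125,62.6,500,500,62.6,62.6,62.6,62.6,62.6,2222
PFDA,female,0.156,0.156,0.312,0.625,1.25,1.25,NA,1.25,NA,11207.8
PFDA,male,0.156,0.156,2.5,0.625,NA,0.156,0.312,0.312,0.312,8505
PFHxA,female,500,500,1000,1000,250,250,NA,NA,NA,475.4
PFHxA,male,500,250,NA,500,62.6,62.6,62.6,62.6,62.6,378.2
PFHxSK,female,3.12,3.12,NA,NA,NA,NA,NA,6.25,12.5,37030
PFHxSK,male,1.25,1.25,NA,10,NA,1.25,0.625,0.625,0.625,66760
PFNA,female,1.56,1.56,1.56,1.56,NA,NA,3.12,3.12,3.12,26400
PFNA,male,0.625,0.625,2.5,1.25,NA,0.625,0.625,0.625,0.625,56730
PFOA,female,25,25,50,100,6.25,50,NA,100,100,2960.1
PFOA,male,0.625,0.625,1.25,0.625,1.25,1.25,0.625,0.625,0.625,50690.2
PFOS,female,0.312,0.312,NA,NA,NA,5,0.312,0.312,0.625,30530
PFOS,male,0.312,0.312,NA,NA,NA,0.312,0.625,0.312,0.312,23730
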