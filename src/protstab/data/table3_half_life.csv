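variant_id,mutations,group,half_life_min
Human P1-1,,reference,9.1
Y109H,Y109H,parent,2.4
V36T-Y109H,V36T-Y109H,rational,2.8
V36L-Y109H,V36L-Y109H,rational,2.3
V1,T35S-Q40L-A46S-Q85R-Y109H,gen1,2.9
V2,Q40M-E41Q-A46S-Y109H-V200L,gen1,1.1
V3,Q40L-S43P-Q85K-Y109H-V200L,gen1,1.7
V4,T35S-E41Q-Q85K-S106T-Y109H,gen1,2.9
V5,Q40M-S43P-Q85R-Y109H-S185C,gen1,5.9
V6,Q85R-C102S-S106T-Y109H-V200L,gen1,10.9
V7,A46S-S106T-Y109H-S185C-V200A,gen1,4.1
V8,Q40L-E41Q-Q84P-Y109H-V200A,gen1,0.94
V9,T35S-S43P-C102S-Y109H-V200A,gen1,1.3
V10,Q40M-Q84P-Q85K-C102S-Y109H,gen1,7.3
V11,T35S-Q84P-Y109H-S185C-V200L,gen1,6.7
V201,T35S-Q40L-E41Q-Q84P-Q85K-S106T-Y109H,gen2,1.4
V202,T35S-Q40L-E41Q-Q85K-S106T-Y109H-S185C,gen2,2.1
V203,T35S-E41Q-Q84P-Q85K-S106T-Y109H-S185C,gen2,6.5
V204,T35S-Q40L-E41Q-Q84P-Q85K-S106T-Y109H-S185C,gen2,1.8
V205,E41Q-Q84P-Q85K-S106T-Y109H-S185C,gen2,6.8
V206,Q40L-E41Q-Q84P-Q85P-S106T-Y109H-S185C,gen2,2.3
V401,Q85R-Y109H,followup,5.6
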