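variant_id,mutations,group,telcyta_score,cdnb_activity,cdnb_sd
Human P1-1,,reference,+++,106,4
Y109H,Y109H,parent,++++,20.9,0.7
Y8H,Y8H,rational,ND,0.08,0.004
Y8E,Y8E,rational,ND,N/D,
F9H-Y109H,F9H-Y109H,rational,ND,0.71,0.01
V11H-Y109H,V11H-Y109H,rational,ND,0.01,0.001
V11A-Y109H,V11A-Y109H,rational,+,17.5,0.4
V11S-Y109H,V11S-Y109H,rational,ND,1.82,0.02
V11T-Y109H,V11T-Y109H,rational,+,5.2,0.2
V11E-Y109H,V11E-Y109H,rational,ND,0.027,0.002
V36R-Y109H,V36R-Y109H,rational,+++,20.6,1.2
V36M-Y109H,V36M-Y109H,rational,++++,24.4,1.1
V36G-Y109H,V36G-Y109H,rational,+++,12.4,0.3
V36L-Y109H,V36L-Y109H,rational,++++,22.0,0.3
V36K-Y109H,V36K-Y109H,rational,++++,27.0,2.5
V36I-Y109H,V36I-Y109H,rational,++++,18.5,0.2
V36T-Y109H,V36T-Y109H,rational,++++,15.6,0.2
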