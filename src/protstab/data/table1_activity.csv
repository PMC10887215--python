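variant_id,mutations,group,telcyta_fold,telcyta_sd,telcyta_score,cdnb_activity,cdnb_sd
Human P1-1,,reference,1,,,106,4
Mouse P1-1,,homolog,0.20,0.06,,76,2.7
Mouse P2-2,,homolog,ND,,,0.10,0.007
Rat P1-1,,homolog,,,+,17,1.0
Dog P1-1,,homolog,,,+,23,1.3
Y8H,Y8H,rational,ND,,,0.08,0.004
Y8E,Y8E,rational,ND,,,ND,
Y109H,Y109H,parent,2.9,0.6,,20.9,0.7
V6,Q85R-C102S-S106T-Y109H-V200L,gen1,3.1,0.9,,28.2,0.3
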