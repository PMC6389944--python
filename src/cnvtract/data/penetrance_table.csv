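label,locus_hg19,n,n_male,n_female,age_mean,age_sd,p_sz,p_dd,notes
15q11.2 BP1-2 deletion,chr15:22805313-23094530,2,1,1,48.4,2.3,2,11,p_dd transcription_uncertain
15q13.3 BP4-5 deletion,chr15:31080645-32462776,2,2,0,30.0,4.5,4.7,35,
15q13.3 BP4-5 duplication,chr15:31080645-32462776,1,1,0,41.7,,1.8,8,
16p11.2 distal duplication,chr16:28823196-29046783,1,0,1,40.3,,0.7,5.3,
16p11.2 deletion,chr16:29650840-30200773,1,1,0,43.0,,0.5,31,p_sz transcription_uncertain
17q12 duplication,chr17:34815904-36217432,1,0,1,47.1,,1.7,17,
1q21.1 deletion,chr1:146527987-147394444,4,4,0,35.0,15.0,5.2,35,
1q21.1 duplication,chr1:146527987-147394444,1,0,1,39.5,,2.9,18,
22q11.2 deletion,chr22:19037332-21466726,4,2,2,31.2,17.0,12,88,
22q11.2 duplication,chr22:19037332-21466726,2,1,1,44.9,4.8,0,14,
3q29 deletion,chr3:195720167-197354826,1,1,0,19.9,,18,53,
NRXN1 deletion,chr2:50145643-51259674,1,1,0,43.6,,6.4,26,
control,,15,6,9,39.6,11.3,0,0,
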