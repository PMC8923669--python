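condition,category,count,percent
control,type1,3,50.0
control,type2,1,16.7
control,type3,1,16.7
control,type4,1,16.7
control,type1_onset_only,1,33.3
control,type1_offset_only,0,0.0
control,type1_both,2,66.7
control,total,6,100.0
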