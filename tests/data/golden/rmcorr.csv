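condition,pairing,r_rm,df,p_value,common_slope,n_subjects
control,onset_area~cs_freezing,0.5632143650870417,7,0.11432300854276291,2.0608362562038494,2
control,offset_area~iti_freezing,0.6898670638083255,7,0.03973843375651268,1.9488493346878606,2
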