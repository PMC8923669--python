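session_id,condition,channel_id,align,phase,onset_latency_ms,peak_latency_ms,peak_to_peak_uV
control_s00,control,ch0,tone_onset,EE,8.0,60.0,455.2488331079146
control_s00,control,ch0,tone_onset,LE,4.0,60.0,287.99847472660747
control_s00,control,ch0,tone_offset,EE,32.0,104.0,446.48149182687285
control_s00,control,ch0,tone_offset,LE,32.0,100.0,283.4215716022103
control_s01,control,ch1,tone_onset,EE,8.0,60.0,456.34241868215133
control_s01,control,ch1,tone_onset,LE,8.0,64.0,287.2255128178675
control_s01,control,ch1,tone_offset,EE,32.0,100.0,454.9652856141895
control_s01,control,ch1,tone_offset,LE,28.0,100.0,277.3523058825478
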