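session_id,condition,unit_id,phase,degenerate,unit_type,subtype,onset_responsive,offset_responsive,area_onset,area_offset,peak_z_onset,peak_z_offset,n_peaks_onset,n_peaks_offset,max_peak_bin_onset,max_peak_bin_offset,excluded_late_peak
control_s00,control,u000,all,False,1,both,True,True,19.20090251874237,15.954765152936393,12.448936797865924,8.7970322613342,1,3,0,0,True
control_s00,control,u000,EE,False,1,both,True,True,28.132750164452766,19.48336281592987,11.777994315160038,6.835487258861239,1,2,0,0,False
control_s00,control,u000,LE,False,1,both,True,True,-0.41408465994060073,-0.7000547289603549,1.615158949823565,1.615158949823565,1,1,0,0,False
control_s00,control,u001,all,False,1,onset_only,True,False,7.47688139422937,-0.2743951911214023,0.9332537008762332,0.5456898716086949,1,0,4,0,True
control_s00,control,u001,EE,False,1,onset_only,True,False,1.3731055000872983,-2.3446891752392944,0.8575713051086679,1.4772037509964335,0,0,2,1,False
control_s00,control,u001,LE,False,1,onset_only,True,False,7.095128996496239,0.9034023954980268,3.047508864186549,1.8681323687583182,1,1,4,3,True
control_s00,control,u002,all,False,3,both_directions,True,True,-13.255787758217503,6.285419119397971,-2.2563042992710645,0.16116459280507645,3,1,4,0,True
control_s00,control,u002,EE,False,3,both_directions,True,True,-7.960137969769889,6.354368449653263,-1.0739060815993902,-0.43770579629169465,0,1,0,0,True
control_s00,control,u002,LE,False,3,both_directions,True,True,-15.475548983750098,-2.900617523498121,-0.6323394105726707,0.565273109451327,0,0,4,1,True
control_s01,control,u000,all,False,1,both,True,True,12.382461311835645,26.278981595533185,5.837420837901136,8.043217708329317,1,2,0,0,True
control_s01,control,u000,EE,False,1,both,True,True,11.792796124571794,23.26566315703824,6.760468847931084,8.071653651641533,1,2,0,0,True
control_s01,control,u000,LE,False,1,both,True,True,4.504338186681812,13.306616314294521,4.904993604904184,3.690886276957604,1,2,0,0,False
control_s01,control,u001,all,False,2,none,False,False,-4.169968019194808,-4.811107013535955,-0.5744605389296663,0.2803914535251944,0,0,1,2,True
control_s01,control,u001,EE,False,2,none,False,False,-3.814211018673206,-0.6071950276363143,1.533666313935866,0.10832587347502409,1,0,1,4,True
control_s01,control,u001,LE,False,2,none,False,False,5.104017688110344,1.875855626863002,0.530592455157745,0.530592455157745,0,1,2,2,True
control_s01,control,u002,all,False,4,none,True,True,-26.589458859153183,-3.5772676798018974,-3.100779956558863,0.5089755225550638,1,1,4,0,True
control_s01,control,u002,EE,False,4,none,True,True,-8.988857381898724,-3.988511325214225,-1.6001107381390396,0.7529932885360185,0,0,4,0,False
control_s01,control,u002,LE,False,4,none,True,True,-16.95382095245141,5.83021677819942,-0.5243449779108683,0.7240954456864374,0,0,4,0,True
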