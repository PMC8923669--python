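session_id,condition,freezing_cs_EE,freezing_iti_EE,freezing_cs_LE,freezing_iti_LE,extinction_slope_cs,extinction_slope_iti,freeze_epoch_baseline_s,move_epoch_baseline_s,epoch_shortfall_baseline,freeze_epoch_EE_s,move_epoch_EE_s,epoch_shortfall_EE,freeze_epoch_LE_s,move_epoch_LE_s,epoch_shortfall_LE,rear_count_cs,rear_count_iti,usv_count_cs,usv_count_iti
control_s00,control,78.2350833626541,68.85763681921472,24.649194640009835,40.500905962904234,-2.4508575879973877,-0.05804300468997242,10.673037964716999,7.735649208315098,False,4.530038245737424,3.5399666666194123,False,4.99286684951876,9.47248643565481,False,2,3,0,2
control_s01,control,54.36391911408489,62.24295161962294,43.718120723541155,43.11714466428589,-0.46796165679952095,-1.9825758679408185,7.730571621249675,4.7127878586243614,False,8.307639738008248,3.091900749248694,False,15.353746528363263,14.747895097118022,False,3,6,1,3
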