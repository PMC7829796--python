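trait,harvest,intercept,fr,ppfd,r_squared
dry_weight,early,-0.49,0.00792,0.00414,0.53
dry_weight,late,-1.28,0.04276,0.01183,0.56
incident_light,early,-0.50,0.00815,0.00520,0.58
incident_light,late,-2.72,0.07946,0.02807,0.74
length,early,13.68,0.1478,-0.0126,0.57
length,late,19.40,0.1305,-0.0315,0.42
width,early,3.276,0.0966,0.0152,0.37
width,late,8.774,0.1385,-0.0025,0.29
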