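# Cohort demographic calibration: group sizes and per-variable summaries
# used by sample_cohort.  Normally distributed variables carry mean/sd and
# are truncated to [low, high]; EDSS/BCVA carry medians (metadata only) and
# are drawn as range/4-SD normals truncated to the printed range.
group,n,variable,mean,sd,low,high
Control,14,age_y,41.0,12.6,20,60
NON,12,age_y,42.0,10.9,27,61
HON,11,age_y,39.0,9.8,25,52
Control,14,female_frac,0.50,,,
NON,12,female_frac,0.667,,,
HON,11,female_frac,0.727,,,
NON,12,duration_y,6.4,4.6,1,13
HON,11,duration_y,10.3,8.0,1,26
Control,14,bcva_logmar,-0.02,0.025,-0.1,0.0
NON,12,bcva_logmar,-0.02,0.05,-0.1,0.1
HON,11,bcva_logmar,0.00,0.05,-0.1,0.1
NON,12,edss,2.0,1.5,1,7
HON,11,edss,1.5,1.125,0,4.5
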