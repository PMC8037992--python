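# Multifocal PERG calibration: group-level amplitude means/SDs (measured
# conventions: N1 from baseline, P1 trough-to-peak, N2 peak-to-trough) and
# peak-time medians/ranges per ring.  ring 0 denotes the summed (global)
# trace.  anchored=0 rows are synthetic fill-ins (the printed ring-2 P1
# amplitude cells duplicate the N2 column, a typesetting artefact, so that
# cell has no usable printed value); they are interpolated between the
# neighbouring rings and excluded from every quantitative check.
group,ring,component,amp_mean_uV,amp_sd_uV,time_median_ms,time_range_ms,anchored
Control,0,N1,-5.36,1.38,25.0,5.0,1
NON,0,N1,-5.05,1.6,25.0,7.5,1
HON,0,N1,-4.5,1.08,24.17,4.17,1
Control,0,P1,11.96,3.05,45.42,8.33,1
NON,0,P1,11.46,3.73,43.33,13.33,1
HON,0,P1,10.44,2.29,42.5,6.67,1
Control,0,N2,-10.55,2.48,73.33,9.17,1
NON,0,N2,-9.82,3.26,72.92,10.0,1
HON,0,N2,-8.86,2.16,73.33,6.67,1
Control,1,N1,-0.5,0.16,27.08,10.83,1
NON,1,N1,-0.41,0.11,25.83,16.67,1
HON,1,N1,-0.4,0.16,25.83,9.17,1
Control,1,P1,1.24,0.37,54.58,11.67,1
NON,1,P1,1.10,0.24,53.33,19.17,1
HON,1,P1,0.92,0.23,52.5,13.33,1
Control,1,N2,-1.5,0.39,75.83,18.33,1
NON,1,N2,-1.16,0.36,75.42,15.83,1
HON,1,N2,-0.97,0.24,76.67,16.67,1
Control,2,N1,-1.05,0.28,25.83,6.67,1
NON,2,N1,-1.01,0.38,25.42,14.17,1
HON,2,N1,-0.86,0.24,24.17,4.17,1
Control,2,P1,2.40,0.50,49.58,10.0,0
NON,2,P1,2.25,0.55,45.83,15.83,0
HON,2,P1,2.00,0.45,43.33,11.67,0
Control,2,N2,-2.06,0.44,73.33,19.17,1
NON,2,N2,-1.77,0.64,72.92,10.0,1
HON,2,N2,-1.51,0.33,72.5,20.0,1
Control,3,N1,-1.84,0.57,25.0,5.0,1
NON,3,N1,-1.69,0.53,24.58,7.5,1
HON,3,N1,-1.40,0.41,23.33,5.0,1
Control,3,P1,4.09,1.0,44.58,8.33,1
NON,3,P1,3.89,1.34,43.33,11.67,1
HON,3,P1,3.4,0.67,41.67,8.33,1
Control,3,N2,-3.4,0.68,72.92,15.83,1
NON,3,N2,-3.21,1.15,71.67,15.0,1
HON,3,N2,-2.7,0.59,73.33,22.5,1
Control,4,N1,-2.02,0.63,25.0,5.0,1
NON,4,N1,-2.00,0.69,24.17,5.0,1
HON,4,N1,-1.88,0.53,24.17,4.17,1
Control,4,P1,5.02,1.49,43.33,9.17,1
NON,4,P1,4.94,1.58,42.5,9.17,1
HON,4,P1,4.62,1.27,41.67,7.5,1
Control,4,N2,-4.52,1.24,70.42,20.83,1
NON,4,N2,-4.35,1.3,70.83,14.17,1
HON,4,N2,-4.1,1.29,72.5,11.67,1
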