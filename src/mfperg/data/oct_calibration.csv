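# OCT calibration: group-level mean [SD] layer thickness (µm) by region.
# Macular regions: center (1 mm ETDRS disc), parafoveal (1-3 mm annulus),
# perifoveal (3-6 mm annulus).  Disc regions: G (global 3.5 mm circle mean),
# PMB (papillomacular bundle), T (temporal sector).  GCIPL is the pointwise
# GCL+IPL sum and is never generated independently.
group,layer,region,mean_um,sd_um
Control,Total,center,279.71,25.63
NON,Total,center,282.67,27.77
HON,Total,center,286.73,28.63
Control,Total,parafoveal,344.43,13.55
NON,Total,parafoveal,337.48,18.45
HON,Total,parafoveal,326.32,17.1
Control,Total,perifoveal,298.89,9.66
NON,Total,perifoveal,293.52,13.32
HON,Total,perifoveal,290.75,13.94
Control,mRNFL,center,12.79,2.75
NON,mRNFL,center,12.33,3.06
HON,mRNFL,center,13.18,2.79
Control,mRNFL,parafoveal,21.95,1.58
NON,mRNFL,parafoveal,22.04,2.39
HON,mRNFL,parafoveal,21.64,2.13
Control,mRNFL,perifoveal,36.14,2.65
NON,mRNFL,perifoveal,36.54,5.9
HON,mRNFL,perifoveal,32.05,5.86
Control,GCL,center,16.00,5.11
NON,GCL,center,17.00,8.5
HON,GCL,center,18.09,11.17
Control,GCL,parafoveal,51.75,3.7
NON,GCL,parafoveal,48.21,6.2
HON,GCL,parafoveal,40.14,6.7
Control,GCL,perifoveal,35.16,2.8
NON,GCL,perifoveal,33.04,2.9
HON,GCL,perifoveal,30.73,3.5
Control,IPL,center,21.43,4.3
NON,IPL,center,22.92,6.9
HON,IPL,center,22.73,6.4
Control,IPL,parafoveal,41.84,2.3
NON,IPL,parafoveal,39.46,4.3
HON,IPL,parafoveal,36.16,3.8
Control,IPL,perifoveal,28.88,1.9
NON,IPL,perifoveal,27.38,2.8
HON,IPL,perifoveal,26.55,2.6
Control,GCIPL,center,18.71,4.63
NON,GCIPL,center,19.96,7.65
HON,GCIPL,center,20.41,8.72
Control,GCIPL,parafoveal,46.79,2.9
NON,GCIPL,parafoveal,43.83,5.2
HON,GCIPL,parafoveal,38.15,5.04
Control,GCIPL,perifoveal,32.02,2.32
NON,GCIPL,perifoveal,30.21,2.76
HON,GCIPL,perifoveal,28.64,3.02
Control,INL,center,20.29,6.91
NON,INL,center,21.42,7.33
HON,INL,center,25.64,10.85
Control,INL,parafoveal,40.82,4.02
NON,INL,parafoveal,39.6,2.98
HON,INL,parafoveal,40.2,2.4
Control,INL,perifoveal,32.52,1.88
NON,INL,perifoveal,32.06,2.66
HON,INL,perifoveal,32.84,1.94
Control,ONL,center,92.71,8.84
NON,ONL,center,94.5,15.22
HON,ONL,center,89.18,19.95
Control,ONL,parafoveal,71.25,5.83
NON,ONL,parafoveal,68.23,8.43
HON,ONL,parafoveal,70.0,6.16
Control,ONL,perifoveal,59.95,5.37
NON,ONL,perifoveal,56.19,5.74
HON,ONL,perifoveal,58.25,4.63
Control,ORL,center,90.86,2.28
NON,ORL,center,91.17,3.35
HON,ORL,center,89.55,6.01
Control,ORL,parafoveal,81.77,1.25
NON,ORL,parafoveal,83.38,2.56
HON,ORL,parafoveal,82.91,2.0
Control,ORL,perifoveal,78.21,1.28
NON,ORL,perifoveal,79.69,1.75
HON,ORL,perifoveal,79.48,2.28
Control,pRNFL,G,94.64,5.84
NON,pRNFL,G,92.92,11.41
HON,pRNFL,G,86.18,12.02
Control,pRNFL,PMB,54.33,11.77
NON,pRNFL,PMB,45.0,6.81
HON,pRNFL,PMB,40.82,8.3
Control,pRNFL,T,71.42,14.89
NON,pRNFL,T,61.17,10.97
HON,pRNFL,T,55.18,10.31
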