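year,browsing,insects,trait,mean,n,unit
2016,control,no,R02,8.68,16,mm
2016,control,yes,R02,9.10,16,mm
2016,clipped,no,R02,7.32,16,mm
2016,clipped,yes,R02,6.18,16,mm
2016,control,no,R075,9.99,16,mm
2016,control,yes,R075,8.19,16,mm
2016,clipped,no,R075,8.42,16,mm
2016,clipped,yes,R075,7.96,16,mm
2016,control,no,H,48.7,16,cm
2016,control,yes,H,47.3,16,cm
2016,clipped,no,H,47.8,16,cm
2016,clipped,yes,H,46.0,16,cm
2017,none,once,R02,20.02,6,mm
2017,none,twice,R02,18.31,7,mm
2017,b2016,once,R02,13.21,8,mm
2017,b2016,twice,R02,14.47,6,mm
2017,b2017,once,R02,15.63,7,mm
2017,b2017,twice,R02,18.69,7,mm
2017,b2016_2017,once,R02,13.36,7,mm
2017,b2016_2017,twice,R02,12.06,8,mm
2017,none,once,R075,22.15,6,mm
2017,none,twice,R075,17.51,7,mm
2017,b2016,once,R075,18.69,8,mm
2017,b2016,twice,R075,18.83,6,mm
2017,b2017,once,R075,17.57,7,mm
2017,b2017,twice,R075,20.27,7,mm
2017,b2016_2017,once,R075,19.17,7,mm
2017,b2016_2017,twice,R075,17.88,8,mm
2017,none,once,H,114.7,6,cm
2017,none,twice,H,110.1,7,cm
2017,b2016,once,H,98.5,8,cm
2017,b2016,twice,H,98.4,6,cm
2017,b2017,once,H,97.3,7,cm
2017,b2017,twice,H,108.2,7,cm
2017,b2016_2017,once,H,107.3,7,cm
2017,b2016_2017,twice,H,104.1,8,cm
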