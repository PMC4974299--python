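genotype_id,treatment,dm,lad,bbch,phyllochron,tiller_n,et_rate,cum_transp,sc,pr,is_cultivar
96,control,8.5,8533.3,33,3.1,3.4,95.5,48.4,507.8,36.4,False
6924,control,5.7,6490.7,34,3.4,2.2,75.7,33.2,637.5,29.5,False
9127,control,5.5,6578.1,42,3.7,1.4,83.0,38.7,535.7,34.9,False
9923,control,5.0,5716.1,26,4.2,3.2,71.3,31.6,506.6,27.7,False
BPR,control,6.9,7276.5,22,5.0,2.8,76.7,34.4,421.0,34.5,False
B-1,control,6.0,6732.2,25,3.7,1.4,80.5,37.2,689.0,32.0,False
Da Terra,control,6.5,6552.7,31,3.7,2.2,76.5,34.2,387.5,19.5,False
ELS114,control,7.5,7944.7,32,3.2,3.0,86.4,41,702.0,31.2,False
ELS63,control,7.1,8204.0,34,3.1,2.4,94.9,45.3,829.1,32.1,False
Floradur,control,5.2,5582.7,35,2.9,1.8,74.0,32.1,762.6,32.8,True
IWA860,control,6.7,7246.2,22,5.0,3.0,81.9,39.2,439.1,25.5,False
Levante,control,4.6,5094.8,28,3.7,1.2,71.6,31.8,560.1,26.2,True
NEDA,control,4.7,5033.4,31,3.2,1.8,66.6,26.5,828.8,36.5,True
S-44,control,7.6,7943.8,19,3.7,1.6,88.4,43,344.1,18.0,False
Ziraat,control,6.8,7720.6,23,3.4,3.4,79.4,36.5,242.8,12.3,False
96,stress,4.9,6189.3,35,2.6,0.8,54.2,26.9,490.6,31.5,False
6924,stress,2.5,3337.6,35,3.7,1.0,36.8,14.4,602.8,31.0,False
9127,stress,2.9,4131,46,3.7,0.8,42.8,19.3,524.8,37.0,False
9923,stress,3.5,4631.3,19,6.1,1.6,45.9,21.1,413.8,25.5,False
BPR,stress,4.2,5117.9,22,5.5,2.6,45.2,20.1,392.0,27.5,False
B-1,stress,3.4,4849.3,26,4.2,2.8,43.9,19.4,481.7,28.2,False
Da Terra,stress,3.5,4037.2,31,3.7,0.8,42.3,18,259.9,17.0,False
ELS114,stress,3.8,5290.2,34,3.9,1.4,45.9,20.6,483.0,27.9,False
ELS63,stress,4.4,5741.4,35,3.1,1.2,54.8,27.2,715.8,35.5,False
Floradur,stress,3.0,3817.5,35,2.8,1.6,40.8,16.9,587.6,33.8,True
IWA860,stress,3.6,4455.8,23,7.9,2.6,40.1,17.4,366.9,27.0,False
Levante,stress,2.5,3236.7,32,3.1,0.6,39.6,16.1,527.4,30.3,True
NEDA,stress,2.9,3516.9,35,3.2,1.4,40.2,16.7,664.7,35.5,True
S-44,stress,4.4,5386.9,25,3.9,1.6,49.8,23.7,284.4,17.3,False
Ziraat,stress,4.5,5504.0,24,6.1,3.6,47.2,21.5,202.3,12.7,False
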