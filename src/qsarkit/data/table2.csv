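descriptor,tolerance,vif,p_value,r_activity
BCUT_SMR_2,0.5117,1.9545,0.0012,-0.34
logP(o/w),0.6216,1.6087,0.0092,0.44
SlogP_VSA4,0.5946,1.6817,<0.0001,0.72
vsurf_IW3,0.6546,1.5277,0.0007,-0.31
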