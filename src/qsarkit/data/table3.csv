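variable,BCUT_SMR_2,logP(o/w),SlogP_VSA4,vsurf_IW3,pIC50
BCUT_SMR_2,1.0000,-0.4640,-0.5413,0.2441,-0.3386
logP(o/w),-0.4640,1.0000,0.0986,-0.5042,0.4451
SlogP_VSA4,-0.5413,0.0986,1.0000,0.1923,0.7195
vsurf_IW3,0.2441,-0.5042,0.1923,1.0000,-0.3148
pIC50,-0.3386,0.4451,0.7195,-0.3148,1.0000
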