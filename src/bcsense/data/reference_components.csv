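method,term,sigma2
raw_camera,W,0.0170
raw_camera,A,0.0375
raw_camera,C,0.0000
raw_camera,WD,0.0005
raw_camera,WA,0.0052
raw_camera,WC,0.0000
raw_camera,AC,0.0014
raw_camera,WDM,0.0000
raw_camera,WDA,0.0000
raw_camera,WDC,0.0000
raw_camera,WAC,0.0000
raw_camera,WDMA,0.0000
raw_camera,WDMC,0.0002
raw_camera,WDAC,0.00092
raw_camera,WDMAC,0.0000
raw_camera,eps,0.0218
refined_camera,W,0.0190
refined_camera,A,0.0463
refined_camera,C,0.0000
refined_camera,WD,0.0004
refined_camera,WA,0.0077
refined_camera,WC,0.0000
refined_camera,AC,0.0006
refined_camera,WDM,0.0000
refined_camera,WDA,0.0006
refined_camera,WDC,0.0000
refined_camera,WAC,0.0000
refined_camera,WDMA,0.0012
refined_camera,WDMC,0.0003
refined_camera,WDAC,0.0000
refined_camera,WDMAC,0.0000
refined_camera,eps,0.0062
visual,W,0.0100
visual,A,0.0736
visual,S,0.0004
visual,WA,0.0094
visual,WS,0.0022
visual,AS,0.0056
visual,eps,0.0186
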