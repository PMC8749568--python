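method,mean_bcs,beta_per_month
raw_camera,4.50,-0.18
refined_camera,4.49,-0.19
visual,4.44,-0.17
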