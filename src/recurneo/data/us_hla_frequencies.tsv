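allele	frequency
HLA-A*01:01	0.0761
HLA-A*02:01	0.2036
HLA-A*03:01	0.0660
HLA-A*11:01	0.0437
HLA-B*07:02	0.0651
HLA-B*08:01	0.0480
HLA-B*15:01	0.0446
HLA-C*04:01	0.1669
HLA-C*06:02	0.0572
HLA-C*07:01	0.0928
HLA-C*07:02	0.1539
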