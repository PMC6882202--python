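# Default class I allele panel (11 frequent HLA-1 types)
HLA-A*01:01
HLA-A*02:01
HLA-A*03:01
HLA-A*11:01
HLA-B*07:02
HLA-B*08:01
HLA-B*15:01
HLA-C*04:01
HLA-C*06:02
HLA-C*07:01
HLA-C*07:02
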