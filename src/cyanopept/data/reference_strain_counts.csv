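group,CPCC 507,CPCC 720,CPCC 731,CPCC 732,CPCC 733,CPCC 735,group_total
cyanopeptolin,31,28,17,11,0,23,80
anabaenopeptin,16,10,14,13,34,12,61
microviridin,11,17,0,0,14,14,35
aeruginosin,0,0,19,0,0,9,28
microcystin,8,4,12,3,6,10,21
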