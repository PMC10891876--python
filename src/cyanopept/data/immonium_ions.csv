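residue,mz
Gly,30.0344
Ala,44.0500
Ser,60.0449
Pro,70.0657
Val,72.0813
Thr,74.0606
Cys,76.0221
Lxx,86.0970
Asn,87.0558
Asp,88.0398
Gln,101.0715
Lys,101.1078
Glu,102.0555
Met,104.0534
His,110.0718
Phe,120.0813
Arg,129.1140
Tyr,136.0762
Trp,159.0922
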