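group,subclass,mz,label,role,note
microcystin,,135.0803,[Adda fragment a]+,required,
microcystin,,163.1113,[Adda fragment b]+,required,
anabaenopeptin,,84.0814,[Lys-related ion]+,required_intense,must be intense relative to base peak
anabaenopeptin,exo-Arg,201.0985,[Arg -CO +H]+,subclass,
anabaenopeptin,exo-Arg,175.1192,[Arg +2H]+,subclass,
anabaenopeptin,exo-Trp,159.0914,[Trp immonium]+,subclass,
anabaenopeptin,exo-Apa,148.1121,[2-amino-5-phenylpentanoic acid immonium]+,subclass,
anabaenopeptin,exo-Ahppa,164.1070,[2-amino-5-hydroxyphenylpentanoic acid immonium]+,subclass,
cyanopeptolin,Thr,197.0919,[Thr-Ahp -H2O +H]+,subclass,
cyanopeptolin,Thr,169.0967,[Thr-Ahp -H2O -CO +H]+,subclass,
cyanopeptolin,Lxx,209.1283,[Lxx-Ahp -H2O +H]+,subclass,
cyanopeptolin,Lxx,181.1331,[Lxx-Ahp -H2O -CO +H]+,subclass,
cyanopeptolin,Phe,243.1121,[Phe-Ahp -H2O +H]+,subclass,
cyanopeptolin,Phe,215.1174,[Phe-Ahp -H2O -CO +H]+,subclass,
cyanopeptolin,Val,195.1490,[Val-Ahp -H2O +H]+,subclass,empirical value kept verbatim; not the CH2 homolog of the Lxx-Ahp ion
cyanopeptolin,Val,167.1541,[Val-Ahp -H2O -CO +H]+,subclass,empirical value kept verbatim
aeruginosin,,140.1064,[Choi immonium-type ion]+,required,empirical; differs from formula-derived mass by ~1 mDa
aeruginosin,,122.0962,[Choi immonium -H2O]+,required,
aeruginosin,Hpla-Phe,284.1268,[Hpla-Phe -CO]+,subclass,
aeruginosin,Hpla-Tyr,300.1232,[Hpla-Tyr -CO]+,subclass,
aeruginosin,Hpla-Phe,318.0876,[Cl-Hpla-Phe -CO +H]+,chlorine_evidence,
aeruginosin,Hpla-Tyr,334.0838,[Cl-Hpla-Tyr -CO +H]+,chlorine_evidence,
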