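element,rfd,csf,std_water_ugL,mac_water_ugL,mpl_turkish,mpl_fsanz,mpl_ec,mpl_who,mpl_codex,mpl_chinese,mpl_fao,mpl_iranian
Fe,0.7,,300,300,,,,100,,,,
Zn,0.3,,3000,5000,,,,100,,,30,
Al,1.0,,200,200,,,,,,0.10,,
Cu,0.04,,2000,1000,,,,30,,,30,
Mn,0.14,,100,50,,,,1,,,,
As,0.0003,1.5,10,50,,2,,,,0.1,,0.6
Se,0.005,,40,10,,,,,,,,
Cr,0.003,0.5,50,50,,,,50,,2.0,,0.03
Ni,0.02,1.7,70,20,,,,0.5,,,,0.05
Pb,0.0035,0.0085,10,10,0.3,0.5,0.3,2.0,0.3,0.5,,0.3
Hg,0.0003,,6,1,0.50,,0.50,1,,,0.50,
Co,0.0003,,50,10,,,,,,,,
Cd,0.001,6.3,3,3,0.05,,0.05,1.00,,0.1,0.5,
B,0.2,,2400,1000,,,,,,,,
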