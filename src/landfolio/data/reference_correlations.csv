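crop_id,banana,organic_banana,cocoa,maize,rice,soybean,balsa,laurel
banana,1.00,0.02,-0.01,-0.06,0.02,0.03,0.04,0.01
organic_banana,0.02,1.00,-0.03,-0.01,-0.03,-0.01,0.02,0.02
cocoa,-0.01,-0.03,1.00,-0.02,0.43,0.36,-0.02,0.03
maize,-0.06,-0.01,-0.02,1.00,0.02,0.01,0.02,-0.01
rice,0.02,-0.03,0.43,0.02,1.00,0.59,-0.02,-0.02
soybean,0.03,-0.01,0.36,0.01,0.59,1.00,0.00,-0.02
balsa,0.04,0.02,-0.02,0.02,-0.02,0.00,1.00,0.08
laurel,0.01,0.02,0.03,-0.01,-0.02,-0.02,0.08,1.00
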