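crop_id,min_return,max_return,mean_return,sd_return
banana,-1557,4804,1786,945
organic_banana,-1897,3913,1040,843
cocoa,-9,473,159,70
maize,-31,600,247,108
rice,170,834,486,101
soybean,-20,313,174,52
balsa,-20,552,271,84
laurel,-71,429,154,70
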