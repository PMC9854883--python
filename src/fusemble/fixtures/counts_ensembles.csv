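classifier,class,tp,fp,fn,tn
SV16,BLT,194,52,56,698
SV16,LCY,232,3,18,747
SV16,MLC,185,96,65,654
SV16,PLC,166,72,84,678
ST9,BLT,188,53,62,697
ST9,LCY,234,1,16,749
ST9,MLC,184,99,66,651
ST9,PLC,170,71,80,679
WAV7,BLT,196,57,54,693
WAV7,LCY,230,0,20,750
WAV7,MLC,184,93,66,657
WAV7,PLC,173,67,77,683
WHV13,BLT,194,49,56,701
WHV13,LCY,236,3,14,747
WHV13,MLC,184,97,66,653
WHV13,PLC,165,72,85,678
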