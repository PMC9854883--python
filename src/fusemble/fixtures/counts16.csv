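classifier,class,tp,fp,fn,tn
Xception,BLT,180,58,70,692
Xception,LCY,217,8,33,742
Xception,MLC,166,129,84,621
Xception,PLC,152,90,98,660
InceptionV3,BLT,156,52,94,698
InceptionV3,LCY,196,6,54,744
InceptionV3,MLC,169,123,81,627
InceptionV3,PLC,155,143,95,607
InceptionResNetV2,BLT,169,67,81,683
InceptionResNetV2,LCY,204,1,46,749
InceptionResNetV2,MLC,164,123,86,627
InceptionResNetV2,PLC,163,109,87,641
ResNet50,BLT,170,74,80,676
ResNet50,LCY,225,8,25,742
ResNet50,MLC,184,162,66,588
ResNet50,PLC,105,72,145,678
ResNet101,BLT,167,70,83,680
ResNet101,LCY,225,10,25,740
ResNet101,MLC,183,159,67,591
ResNet101,PLC,111,75,139,675
ResNeXt50,BLT,173,62,77,688
ResNeXt50,LCY,219,3,31,747
ResNeXt50,MLC,156,132,94,618
ResNeXt50,PLC,147,108,103,642
ResNeXt101,BLT,172,59,78,691
ResNeXt101,LCY,226,2,24,748
ResNeXt101,MLC,166,127,84,623
ResNeXt101,PLC,155,93,95,657
SeResNeXt50,BLT,194,116,56,634
SeResNeXt50,LCY,221,4,29,746
SeResNeXt50,MLC,160,110,90,640
SeResNeXt50,PLC,124,71,126,679
SeResNeXt101,BLT,190,105,60,645
SeResNeXt101,LCY,222,2,28,748
SeResNeXt101,MLC,146,103,104,647
SeResNeXt101,PLC,132,100,118,650
EfficientNetB0,BLT,165,61,85,689
EfficientNetB0,LCY,207,2,43,748
EfficientNetB0,MLC,161,114,89,636
EfficientNetB0,PLC,161,129,89,621
EfficientNetB1,BLT,153,100,97,650
EfficientNetB1,LCY,194,11,56,739
EfficientNetB1,MLC,144,142,106,608
EfficientNetB1,PLC,137,119,113,631
EfficientNetB2,BLT,179,114,71,636
EfficientNetB2,LCY,208,10,42,740
EfficientNetB2,MLC,124,98,126,652
EfficientNetB2,PLC,153,114,97,636
EfficientNetB3,BLT,151,75,99,675
EfficientNetB3,LCY,209,9,41,741
EfficientNetB3,MLC,165,162,85,588
EfficientNetB3,PLC,136,93,114,657
EfficientNetB4,BLT,134,84,116,666
EfficientNetB4,LCY,207,7,43,743
EfficientNetB4,MLC,126,145,124,605
EfficientNetB4,PLC,150,147,100,603
EfficientNetB5,BLT,148,64,102,686
EfficientNetB5,LCY,218,6,32,744
EfficientNetB5,MLC,151,129,99,621
EfficientNetB5,PLC,145,139,105,611
EfficientNetB6,BLT,156,79,94,671
EfficientNetB6,LCY,213,14,37,736
EfficientNetB6,MLC,159,147,91,603
EfficientNetB6,PLC,132,100,118,650
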