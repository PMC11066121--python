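run,investigator,mode,target_1,target_2,target_3,target_4,target_5,target_6,target_7,fre_mm,time_s
1,1,EC,6.5,4.7,5.4,0.9,5.3,2.5,4.1,1.2,211
2,1,AS,4.9,6.3,9.7,1.6,8.9,5.9,6.7,1.2,296
3,1,EC+AS,2.8,0.7,1.4,3.1,2.9,3.0,5.5,1.2,192
4,2,EC+AS,0.6,6.2,3.6,2.5,2.7,1.8,1.0,1.1,435
5,3,EC+AS,3.2,5.1,6.4,0.9,2.1,1.7,1.0,1.1,319
6,4,EC+AS,3.0,5.8,6.4,3.2,6.7,6.2,7.0,1.2,310
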