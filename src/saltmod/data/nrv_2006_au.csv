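age_band,gender,sodium_ai_low,sodium_ai_high,sodium_ul,iodine_rdi,iodine_ear,iodine_ul,ref_weight_kg,eer_offset_mj
0-0.5,M,120,120,,90,,,6.0,0.0
0-0.5,F,120,120,,90,,,6.0,0.0
0.5-1,M,170,170,,110,,,9.0,0.0
0.5-1,F,170,170,,110,,,9.0,0.0
1-3,M,200,400,1000,90,65,200,13.0,0.0
1-3,F,200,400,1000,90,65,200,13.0,0.0
4-8,M,300,600,1400,90,65,300,22.0,0.0
4-8,F,300,600,1400,90,65,300,22.0,0.0
9-13,M,400,800,2000,120,75,600,40.0,0.0
9-13,F,400,800,2000,120,75,600,40.0,0.0
14-18,M,460,920,2300,150,95,900,64.0,0.0
14-18,F,460,920,2300,150,95,900,57.0,0.0
19-30,M,460,920,2300,150,100,1100,,0.0
19-30,F,460,920,2300,150,100,1100,,0.0
31-50,M,460,920,2300,150,100,1100,,0.0
31-50,F,460,920,2300,150,100,1100,,0.0
51-70,M,460,920,2300,150,100,1100,,0.0
51-70,F,460,920,2300,150,100,1100,,0.0
71+,M,460,920,2300,150,100,1100,,0.0
71+,F,460,920,2300,150,100,1100,,0.0
pregnancy,F,460,920,2300,220,160,1100,,1.4
lactation,F,460,920,2300,270,190,1100,,2.0
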