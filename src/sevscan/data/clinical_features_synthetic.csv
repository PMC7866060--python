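sample_id,sex,age,hemifacial_microsomia,mandibular_hypoplasia,cleft_lip_palate,ear_anomalies,ocular_anomalies,vertebral_anomalies,cardiovascular_anomalies,genitourinary_anomalies,brain_anomalies,developmental_delay,radial_defects,other_organ_anomalies
P01,M,37.9,1,1,0,1,1,0,1,0,0,0,0,0
P02,F,23.1,1,1,0,1,1,0,0,0,0,0,0,0
P03,M,5.3,1,1,1,1,1,0,0,0,0,0,0,0
P04,M,2.1,1,1,0,1,1,0,0,0,0,1,0,0
P05,M,1.3,1,1,0,1,1,0,1,1,1,0,0,0
P06,F,10.4,1,1,0,1,0,0,0,0,1,0,0,0
P07,M,13.9,1,1,0,1,1,0,1,0,0,0,0,0
P08,M,36.4,1,1,0,1,1,0,1,0,0,0,0,0
P09,F,27.4,1,1,0,1,1,0,0,0,0,0,0,0
P10,F,1.1,1,1,0,1,0,0,1,1,1,0,0,1
P11,M,1.3,0,1,0,1,0,0,1,0,0,1,0,0
P12,F,5.1,0,1,0,1,1,1,0,0,0,0,0,1
P13,F,4.4,1,1,1,1,0,0,0,0,0,1,0,0
P14,M,42.7,1,0,0,1,1,0,0,1,1,0,0,0
P15,F,3.9,1,1,0,1,0,0,1,0,0,0,0,0
P16,F,4.8,1,1,0,1,0,0,1,0,0,0,1,0
P17,M,1.1,1,1,0,1,0,0,0,0,0,0,0,1
P18,F,28.0,1,1,0,1,0,0,1,1,0,1,1,1
P19,M,2.0,1,1,1,1,1,0,0,0,1,0,0,0
P20,M,13.5,1,1,0,1,1,1,0,1,0,1,0,0
P21,F,0.2,1,0,1,1,0,0,0,0,0,0,0,0
P22,M,1.2,1,1,1,1,0,0,0,0,0,0,0,0
P23,F,4.6,1,0,1,1,1,0,0,0,0,0,0,0
P24,M,8.1,1,1,0,1,1,1,1,0,0,0,0,0
P25,M,5.2,1,1,0,1,1,0,1,0,0,0,0,0
P26,M,11.1,1,1,0,1,1,1,0,1,0,0,0,0
P27,M,6.0,1,1,0,1,1,1,0,0,0,1,0,0
P28,M,10.1,1,1,0,1,0,0,0,0,0,0,0,0
P29,F,18.0,1,0,0,1,1,1,1,0,0,0,0,0
P30,F,0.4,1,1,0,1,0,1,0,0,0,1,1,0
P31,M,3.1,1,1,0,1,0,0,1,0,0,0,0,0
P32,F,29.2,1,1,0,1,1,0,0,1,0,0,0,0
P33,F,13.7,1,1,1,1,0,0,1,0,0,0,0,0
P34,M,20.1,1,1,0,1,1,1,0,0,0,0,0,0
P35,F,5.5,1,1,0,1,1,0,0,0,0,0,0,1
P36,M,6.2,1,1,0,1,0,1,0,0,1,1,0,1
P37,M,4.8,1,1,1,1,1,0,0,0,0,1,0,1
P38,M,1.8,1,1,0,1,0,1,1,0,1,0,0,1
P39,F,8.4,1,1,0,1,1,1,0,0,0,0,0,0
P40,F,37.7,1,1,0,1,1,0,0,0,0,0,0,0
P41,F,7.5,1,1,0,1,0,1,0,0,0,0,0,0
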