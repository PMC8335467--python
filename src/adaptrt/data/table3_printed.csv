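panel,row,approach,value,sd
criterion,ptv_v36.25,REFERENCE,47,
criterion,ptv_v36.25,IGRT,544,
criterion,ptv_v36.25,ART1,93,
criterion,ptv_v36.25,ART2,66,
criterion,ptv_v36.25,ART3,262,
criterion,ptv_d98,REFERENCE,9,
criterion,ptv_d98,IGRT,852,
criterion,ptv_d98,ART1,88,
criterion,ptv_d98,ART2,69,
criterion,ptv_d98,ART3,16,
criterion,bladder_v37,REFERENCE,0,
criterion,bladder_v37,IGRT,1800,
criterion,bladder_v37,ART1,292,
criterion,bladder_v37,ART2,333,
criterion,bladder_v37,ART3,92,
criterion,rectum_v36,REFERENCE,0,
criterion,rectum_v36,IGRT,5943,
criterion,rectum_v36,ART1,1424,
criterion,rectum_v36,ART2,1754,
criterion,rectum_v36,ART3,254,
total,total,REFERENCE,56,
total,total,IGRT,9139,
total,total,ART1,1897,
total,total,ART2,2222,
total,total,ART3,624,
patient,P1,REFERENCE,2.0,
patient,P1,IGRT,14.2,10.6
patient,P1,ART1,1.0,0.5
patient,P1,ART2,0.3,0.4
patient,P1,ART3,1.6,0.9
patient,P2,REFERENCE,3.0,
patient,P2,IGRT,35.0,36.5
patient,P2,ART1,3.4,0.7
patient,P2,ART2,1.3,0.4
patient,P2,ART3,2.3,1.0
patient,P3,REFERENCE,1.6,
patient,P3,IGRT,67.7,54.9
patient,P3,ART1,0.1,0.2
patient,P3,ART2,5.9,9.7
patient,P3,ART3,1.2,0.8
patient,P4,REFERENCE,2.3,
patient,P4,IGRT,77.3,51.0
patient,P4,ART1,27.7,22.7
patient,P4,ART2,33.7,25.7
patient,P4,ART3,21.0,28.7
patient,P5,REFERENCE,1.0,
patient,P5,IGRT,24.9,25.2
patient,P5,ART1,8.2,15.7
patient,P5,ART2,5.0,9.8
patient,P5,ART3,0.5,0.6
patient,P6,REFERENCE,1.5,
patient,P6,IGRT,84.5,104.9
patient,P6,ART1,22.5,33.6
patient,P6,ART2,17.8,33.5
patient,P6,ART3,2.9,2.7
patient,P7,REFERENCE,4.1,
patient,P7,IGRT,82.5,51.5
patient,P7,ART1,15.8,20.3
patient,P7,ART2,19.5,25.0
patient,P7,ART3,9.3,14.0
patient,P8,REFERENCE,1.0,
patient,P8,IGRT,80.5,64.4
patient,P8,ART1,17.7,25.2
patient,P8,ART2,20.4,21.4
patient,P8,ART3,1.7,1.6
patient,P9,REFERENCE,1.8,
patient,P9,IGRT,9.9,10.1
patient,P9,ART1,0.1,0.2
patient,P9,ART2,0,0.1
patient,P9,ART3,1.4,0.1
patient,P10,REFERENCE,10.2,
patient,P10,IGRT,94.5,85.3
patient,P10,ART1,20.8,13.8
patient,P10,ART2,18.7,8.5
patient,P10,ART3,4.8,0.7
patient,P11,REFERENCE,1.2,
patient,P11,IGRT,18.9,20.1
patient,P11,ART1,0.1,0.1
patient,P11,ART2,0.1,0.2
patient,P11,ART3,0.7,0.6
patient,P12,REFERENCE,1.9,
patient,P12,IGRT,34.3,23.7
patient,P12,ART1,1.5,1.9
patient,P12,ART2,0.3,0.6
patient,P12,ART3,2.0,0.5
patient,P13,REFERENCE,0,
patient,P13,IGRT,25.8,20.0
patient,P13,ART1,0.9,1.8
patient,P13,ART2,0,0
patient,P13,ART3,1.4,1.1
patient,P14,REFERENCE,0.8,
patient,P14,IGRT,157.6,218.6
patient,P14,ART1,39.8,75.4
patient,P14,ART2,40.9,77.8
patient,P14,ART3,19.9,29.5
patient,P15,REFERENCE,2.0,
patient,P15,IGRT,58.4,55.9
patient,P15,ART1,13.6,21.9
patient,P15,ART2,17.7,21.8
patient,P15,ART3,2.7,1.1
patient,P16,REFERENCE,0,
patient,P16,IGRT,4.8,4.4
patient,P16,ART1,0,0.1
patient,P16,ART2,0,0
patient,P16,ART3,0,0.1
patient,P17,REFERENCE,1.2,
patient,P17,IGRT,38.3,32.2
patient,P17,ART1,3.3,6.3
patient,P17,ART2,8.5,10.1
patient,P17,ART3,2.4,0.7
patient,P18,REFERENCE,0.4,
patient,P18,IGRT,17.0,14.5
patient,P18,ART1,0.8,1.0
patient,P18,ART2,0.8,1.0
patient,P18,ART3,1.1,0.7
patient,P19,REFERENCE,2.5,
patient,P19,IGRT,58.3,63.5
patient,P19,ART1,5.7,5.5
patient,P19,ART2,6.1,6.7
patient,P19,ART3,1.8,1.3
patient,P20,REFERENCE,2.2,
patient,P20,IGRT,56.2,24.0
patient,P20,ART1,7.1,5.8
patient,P20,ART2,8.3,5.6
patient,P20,ART3,1.9,0.7
patient,P21,REFERENCE,0,
patient,P21,IGRT,7.3,13.5
patient,P21,ART1,0.6,0.6
patient,P21,ART2,0.3,0.7
patient,P21,ART3,0,0
patient,P22,REFERENCE,1.1,
patient,P22,IGRT,70.6,21.4
patient,P22,ART1,24.7,15.3
patient,P22,ART2,19.1,14.0
patient,P22,ART3,6.6,8.7
patient,P23,REFERENCE,2.2,
patient,P23,IGRT,46.0,47.2
patient,P23,ART1,24.5,32.4
patient,P23,ART2,17.0,22.0
patient,P23,ART3,1.8,0.6
patient,P24,REFERENCE,0,
patient,P24,IGRT,288.7,115.4
patient,P24,ART1,53.8,51.1
patient,P24,ART2,81.2,76.3
patient,P24,ART3,24.6,35.2
patient,P25,REFERENCE,5.0,
patient,P25,IGRT,57.7,51.8
patient,P25,ART1,10.0,9.2
patient,P25,ART2,18.2,18.2
patient,P25,ART3,4.1,0.6
patient,P26,REFERENCE,4.2,
patient,P26,IGRT,15.5,14.9
patient,P26,ART1,2.3,1.6
patient,P26,ART2,1.2,1.7
patient,P26,ART3,1.8,1.0
patient,P27,REFERENCE,0,
patient,P27,IGRT,71.5,44.4
patient,P27,ART1,29.5,23.6
patient,P27,ART2,41.1,31.2
patient,P27,ART3,3.2,3.7
patient,P28,REFERENCE,1.0,
patient,P28,IGRT,12.7,25.4
patient,P28,ART1,0.6,0.5
patient,P28,ART2,0.7,1.1
patient,P28,ART3,0.4,0.4
patient,P29,REFERENCE,0.5,
patient,P29,IGRT,210.2,108.7
patient,P29,ART1,43.1,21.9
patient,P29,ART2,59.9,29.7
patient,P29,ART3,1.2,1.3
patient,P30,REFERENCE,0.0,
patient,P30,IGRT,2.1,3.1
patient,P30,ART1,0,0
patient,P30,ART2,0,0
patient,P30,ART3,0,0
patient,P31,REFERENCE,1.2,
patient,P31,IGRT,0.9,0.6
patient,P31,ART1,0,0
patient,P31,ART2,0.1,0.3
patient,P31,ART3,0.4,0.4
patient,P32,REFERENCE,0.0,
patient,P32,IGRT,3.9,7.7
patient,P32,ART1,0.1,0.1
patient,P32,ART2,0.2,0.4
patient,P32,ART3,0,0
mean,mean,REFERENCE,1.7,2.0
mean,mean,IGRT,57.1,87.4
mean,mean,ART1,11.9,25.7
mean,mean,ART2,13.9,30.6
mean,mean,ART3,3.9,11.8
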