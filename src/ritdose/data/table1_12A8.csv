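antibody,tissue,day,mean_pid_g,sd_pid_g,n
12A8,Blood,1,12.5,0.7,5
12A8,Blood,2,11.5,2.6,5
12A8,Blood,4,7.6,0.7,5
12A8,Blood,7,3.7,1.2,5
12A8,Blood,10,3.7,0.9,5
12A8,Lung,1,3.0,0.1,5
12A8,Lung,2,3.3,0.6,5
12A8,Lung,4,2.5,0.4,5
12A8,Lung,7,1.6,0.3,5
12A8,Lung,10,1.8,0.6,5
12A8,Liver,1,5.3,0.5,5
12A8,Liver,2,4.8,0.8,5
12A8,Liver,4,4.0,0.5,5
12A8,Liver,7,4.0,0.6,5
12A8,Liver,10,2.7,0.5,5
12A8,Spleen,1,2.8,0.1,5
12A8,Spleen,2,3.4,1.1,5
12A8,Spleen,4,2.3,0.7,5
12A8,Spleen,7,2.0,0.4,5
12A8,Spleen,10,2.0,0.4,5
12A8,Stomach,1,0.6,0.1,5
12A8,Stomach,2,0.5,0.2,5
12A8,Stomach,4,0.5,0.1,5
12A8,Stomach,7,0.3,0.1,5
12A8,Stomach,10,0.2,0.1,5
12A8,Intestine,1,1.1,0.1,5
12A8,Intestine,2,1.2,0.3,5
12A8,Intestine,4,0.8,0.1,5
12A8,Intestine,7,0.5,0.1,5
12A8,Intestine,10,0.5,0.2,5
12A8,Kidney,1,8.7,0.5,5
12A8,Kidney,2,8.3,1.4,5
12A8,Kidney,4,5.3,0.4,5
12A8,Kidney,7,3.6,0.6,5
12A8,Kidney,10,2.6,0.6,5
12A8,Muscle,1,0.9,0.1,5
12A8,Muscle,2,0.9,0.2,5
12A8,Muscle,4,0.6,0.1,5
12A8,Muscle,7,0.4,0.0,5
12A8,Muscle,10,0.4,0.1,5
12A8,Bone,1,1.2,0.2,5
12A8,Bone,2,1.4,0.3,5
12A8,Bone,4,1.3,0.2,5
12A8,Bone,7,0.6,0.1,5
12A8,Bone,10,1.2,0.6,5
12A8,Tumor,1,7.3,1.3,5
12A8,Tumor,2,16.7,1.5,5
12A8,Tumor,4,18.9,2.9,5
12A8,Tumor,7,11.1,2.1,5
12A8,Tumor,10,13.4,5.7,5
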