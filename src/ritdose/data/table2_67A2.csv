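antibody,tissue,day,mean_pid_g,sd_pid_g,n
67A2,Blood,1,17.0,2.8,5
67A2,Blood,2,13.7,0.5,5
67A2,Blood,4,10.2,0.5,5
67A2,Blood,7,4.5,1.6,5
67A2,Blood,10,4.4,2.0,5
67A2,Lung,1,4.2,0.5,5
67A2,Lung,2,4.2,0.7,5
67A2,Lung,4,3.4,0.7,5
67A2,Lung,7,1.6,0.5,5
67A2,Lung,10,1.7,0.6,5
67A2,Liver,1,4.7,0.3,5
67A2,Liver,2,4.9,0.7,5
67A2,Liver,4,4.1,0.7,5
67A2,Liver,7,4.1,1.0,5
67A2,Liver,10,2.9,0.4,5
67A2,Spleen,1,3.5,0.4,5
67A2,Spleen,2,3.2,0.4,5
67A2,Spleen,4,2.7,0.4,5
67A2,Spleen,7,2.4,0.7,5
67A2,Spleen,10,3.0,0.4,5
67A2,Stomach,1,0.7,0.3,5
67A2,Stomach,2,0.8,0.2,5
67A2,Stomach,4,0.5,0.2,5
67A2,Stomach,7,0.6,0.3,5
67A2,Stomach,10,0.4,0.1,5
67A2,Intestine,1,1.4,0.1,5
67A2,Intestine,2,1.4,0.1,5
67A2,Intestine,4,1.1,0.1,5
67A2,Intestine,7,0.8,0.4,5
67A2,Intestine,10,0.5,0.1,5
67A2,Kidney,1,4.9,0.7,5
67A2,Kidney,2,4.1,0.2,5
67A2,Kidney,4,3.7,0.2,5
67A2,Kidney,7,2.2,0.3,5
67A2,Kidney,10,2.1,0.5,5
67A2,Muscle,1,1.0,0.2,5
67A2,Muscle,2,1.0,0.2,5
67A2,Muscle,4,0.9,0.2,5
67A2,Muscle,7,0.4,0.1,5
67A2,Muscle,10,0.5,0.1,5
67A2,Bone,1,1.5,0.3,5
67A2,Bone,2,1.2,0.2,5
67A2,Bone,4,1.3,0.2,5
67A2,Bone,7,0.8,0.4,5
67A2,Bone,10,0.8,0.2,5
67A2,Tumor,1,15.7,0.9,5
67A2,Tumor,2,23.8,1.6,5
67A2,Tumor,4,31.5,7.7,5
67A2,Tumor,7,18.2,2.2,5
67A2,Tumor,10,16.7,3.0,5
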