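Patient,Sex,Age (years),Environment of Origin,ADK diagnoses,PET-CT/CT,Neoadjuvant Treatment,Smoking,BMI categories,Histology,Stage of diagnosis after surgery,Appetite Loss,Weight Loss,Fever,Rectal Bleeding,Intestinal Transit Disorders,Drinking Alcohol,Diabetes,Anemia,Hemorrhoids,Iron serum (ug/dL),Hg preoperative (g/dL),Hg 7 days postoperative (g/dL),RDW-SD preoperative (fL),RDW-SD at 7 days postoperative (fL),Rayan score
P1,F,45,urban,ML-R,PET-CT,RCT,no,nw,G2,I,yes,yes,no,yes,yes,no,dz type II,no,internal,82,13.5,12.5,49.9,47,1
P2,M,67,urban,L-R,CT,RCT,yes,uw,G1,II,yes,yes,no,yes,yes,rarely,no,no,no,113,15.9,13.5,45.8,43.1,3
P3,M,66,rural,S-C,CT,RCT,yes,uw,G2,IV,yes,yes,no,no,yes,yes,no,yes,no,25,10.5,10.2,48.4,53.8,
P4,M,67,urban,LGM-C,CT,NO,no,uw,G2,III,yes,yes,yes,no,yes,no,dz type II,no,no,30,13.3,12.2,53.2,51.1,
P5,M,81,urban,L-R,CT,RCT,no,nw,G2,0,no,yes,no,yes,yes,rarely,no,yes,internal,40,10.2,9.9,46.8,45.6,0
P6,M,67,urban,MD-CRC,CT,NO,yes,nw,G2,III,yes,yes,no,yes,yes,rarely,dz type II,no,internal,60,13.0,12.9,45.4,45.5,
P7,F,72,urban,MD-R,CT,RCT,no,uw,G2,I,yes,yes,no,yes,yes,no,no,no,Int. & ext.,67,12.5,10.5,48.3,47.3,3
P8,M,81,urban,CR,CT,NO,no,nw,G1,I,no,yes,no,yes,yes,rarely,no,no,internal,33,13.4,11.3,54,53.2,
P9,F,55,urban,MD-C,CT,NO,yes,uw,G2,III,yes,yes,no,yes,yes,rarely,no,yes,no,10,8.9,11.6,79.3,89.9,
P10,M,75,urban,WD-C,CT,NO,yes,uw,G1,III,yes,yes,no,yes,yes,rarely,no,yes,internal,8,7.9,10.7,44.1,66.4,
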