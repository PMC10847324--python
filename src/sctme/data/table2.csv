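sample_id,patient,tissue,site,n_cells,epithelial,ESC,endothelial,fibroblast,MSC,macrophage,B,plasma_B,T,CK7,VIM,CD45,category
P1-1,P1,Omentum,metastatic,2227,59.5,4.5,1.1,22.9,3.6,4.5,0.6,1,2.3,59.2,60,7.9,Low
P1-2,P1,Left Ovary,primary,1156,66.2,3.7,2.7,21.8,2.6,1.1,0,1,1,68.7,37.5,0.4,Low
P1-3,P1,Right Ovary,primary,1051,76.6,5.3,0.9,10.1,3.4,0.9,0,0.7,2.2,66.6,50.2,6.1,Low
P2-1,P2,Omentum,metastatic,1008,54.6,8.1,1,8.7,1.7,10.6,0,2.9,12.3,66.6,79.4,58.9,High
P2-2,P2,Right Ovary,primary,330,28.2,6.1,0.6,21.8,3.9,6.4,0,10.9,22.1,89.3,70.6,34,High
P3-1,P3,Rectum,metastatic,345,26.6,2.4,1.7,27.1,20.4,16.4,0.1,0.3,5.1,69.8,37.9,4.4,Low
P3-2,P3,Left Ovary,primary,928,42.3,3.8,3.8,24.9,14.5,9,0,0,1.7,70.7,40.5,0.7,Low
P4-1,P4,Left Ovary,primary,837,37.2,9.2,1.2,9.4,2.5,35.6,0.1,0.6,4.2,76.4,55.3,0.8,Low
P5-1,P5,Right Ovary,primary,2554,45.7,11.4,0.4,18.7,2.4,5.6,0,3.7,12.1,84.6,54,17.8,High
P6-1,P6,Omentum,metastatic,3357,28.3,6.5,1,22.6,2,9.1,8.8,3.8,17.4,57.5,54.6,17.3,High
P6-2,P6,Left Ovary,primary,2102,60.7,15.2,1.6,11.5,4.8,2.6,0,0.3,2.6,69.1,34.4,9.8,Low
P7-1,P7,Omentum,metastatic,3542,43.7,5.6,4,10.9,1.5,12.1,2.1,7.7,12.5,41.7,69.1,28.5,High
P8-1,P8,Right Ovary,primary,359,70.2,9.6,1.9,5.8,2.1,5.4,0,0.6,4.3,83,39.2,3.3,Low
P8-2,P8,Left Ovary,primary,467,55.7,7.2,3.9,5.9,6.4,11.7,0,0.6,8.6,85.5,51.2,2.5,Low
P9-1,P9,Omentum,metastatic,529,32.9,2.8,2.8,19.1,5.1,16.6,0.2,5.7,14.7,38.9,48,4.4,High
P9-2,P9,Omentum,metastatic,585,35.6,2.1,3.1,40.9,4.4,8,0,3.4,2.6,50.6,49.4,5.4,Low
P9-3,P9,Left Ovary,primary,341,38.7,1.8,0,36.1,10.3,9.4,0,1.2,2.4,84.2,34,2.5,Low
P9-4,P9,Right Ovary,primary,378,30.2,1.9,1.9,38.6,9.3,13.8,0,0,4.2,78.1,41.7,2.3,Low
P10-1,P10,Omentum,metastatic,1067,27.7,8.1,2.4,34.3,1.6,17.2,1,2.2,5.5,21,59.3,10.7,Low
P11-1,P11,Omentum,metastatic,1066,56.9,21.2,0.2,2.9,0.4,10.4,0.3,2.5,5.2,57.8,77.9,23.7,Low
P12-1,P12,Omentum,metastatic,1097,43.3,5.6,4.4,37.4,5.3,1.3,0.5,1,1.2,78.8,44.4,4,Low
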