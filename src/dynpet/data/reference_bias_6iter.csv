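config,structure,model,parameter,bias_pct,sd_pct
SAFOV,tumor_r_border,2tcm,K1,29.1,4.4
SAFOV,tumor_r_border,2tcm,k2,19.4,8.0
SAFOV,tumor_r_border,2tcm,k3,48.6,5.0
SAFOV,tumor_r_border,2tcm,vb,7.8,5.2
SAFOV,tumor_r_border,2tcm,Ki,44.2,2.1
SAFOV,tumor_r_center,2tcm,K1,20.6,16.8
SAFOV,tumor_r_center,2tcm,k2,20.1,12.4
SAFOV,tumor_r_center,2tcm,k3,50.6,12.9
SAFOV,tumor_r_center,2tcm,vb,86.5,31.7
SAFOV,tumor_r_center,2tcm,Ki,39.3,7.2
SAFOV,tumor_l_border,2tcm,K1,19.4,3.2
SAFOV,tumor_l_border,2tcm,k2,20.4,4.6
SAFOV,tumor_l_border,2tcm,k3,43.2,3.7
SAFOV,tumor_l_border,2tcm,vb,5.1,4.1
SAFOV,tumor_l_border,2tcm,Ki,34.6,1.8
SAFOV,tumor_l_center,2tcm,K1,12.0,9.1
SAFOV,tumor_l_center,2tcm,k2,18.1,10.2
SAFOV,tumor_l_center,2tcm,k3,35.1,7.6
SAFOV,tumor_l_center,2tcm,vb,21.1,13.5
SAFOV,tumor_l_center,2tcm,Ki,13.3,4.8
SAFOV,liver,2tcm,K1,5.0,3.4
SAFOV,liver,2tcm,k2,51.5,1.8
SAFOV,liver,2tcm,k3,70.4,1.3
SAFOV,liver,2tcm,vb,34.4,2.3
SAFOV,liver,2tcm,Ki,54.4,1.3
SAFOV,lungs,2tcm,K1,61.1,6.8
SAFOV,lungs,2tcm,k2,29.2,2.7
SAFOV,lungs,2tcm,k3,38.9,2.6
SAFOV,lungs,2tcm,vb,14.9,3.1
SAFOV,lungs,2tcm,Ki,19.7,3.0
SAFOV,bone,2tcm,K1,5.5,3.1
SAFOV,bone,2tcm,k2,28.2,2.3
SAFOV,bone,2tcm,k3,55.9,1.5
SAFOV,bone,2tcm,vb,36.8,2.3
SAFOV,bone,2tcm,Ki,47.0,1.2
SAFOV,heart,2tcm,K1,20.5,3.8
SAFOV,heart,2tcm,k2,55.5,2.0
SAFOV,heart,2tcm,k3,64.6,1.4
SAFOV,heart,2tcm,vb,3.1,2.2
SAFOV,heart,2tcm,Ki,46.9,1.3
SAFOV,spleen,2tcm,K1,62.9,3.6
SAFOV,spleen,2tcm,k2,78.3,1.7
SAFOV,spleen,2tcm,k3,85.0,2.3
SAFOV,spleen,2tcm,vb,80.9,2.0
SAFOV,spleen,2tcm,Ki,81.1,1.8
SAFOV,muscle,2tcm,K1,15.5,1.8
SAFOV,muscle,2tcm,k2,21.6,1.2
SAFOV,muscle,2tcm,k3,3.0,2.0
SAFOV,muscle,2tcm,vb,160.5,15.0
SAFOV,muscle,2tcm,Ki,31.5,1.6
SAFOV,fat,2tcm,K1,13.1,3.2
SAFOV,fat,2tcm,k2,45.7,1.2
SAFOV,fat,2tcm,k3,40.0,1.6
SAFOV,fat,2tcm,vb,69.0,7.2
SAFOV,fat,2tcm,Ki,22.5,1.8
SAFOV,tumor_r_border,patlak,Ki,23.3,2.4
SAFOV,tumor_r_border,patlak,vb,32.6,12.3
SAFOV,tumor_r_center,patlak,Ki,15.1,7.9
SAFOV,tumor_r_center,patlak,vb,55.6,28.9
SAFOV,tumor_l_border,patlak,Ki,11.3,2.0
SAFOV,tumor_l_border,patlak,vb,43.0,10.4
SAFOV,tumor_l_center,patlak,Ki,15.9,6.3
SAFOV,tumor_l_center,patlak,vb,62.5,18.4
SAFOV,liver,patlak,Ki,30.1,2.1
SAFOV,liver,patlak,vb,24.0,6.7
SAFOV,lungs,patlak,Ki,42.0,3.5
SAFOV,lungs,patlak,vb,24.9,7.1
SAFOV,bone,patlak,Ki,5.1,1.5
SAFOV,bone,patlak,vb,19.0,6.5
SAFOV,heart,patlak,Ki,9.6,1.6
SAFOV,heart,patlak,vb,50.7,8.4
SAFOV,spleen,patlak,Ki,43.7,5.1
SAFOV,spleen,patlak,vb,53.2,5.1
SAFOV,muscle,patlak,Ki,11.7,2.0
SAFOV,muscle,patlak,vb,15.1,6.4
SAFOV,fat,patlak,Ki,39.7,2.1
SAFOV,fat,patlak,vb,63.8,8.9
LAFOV,tumor_r_border,2tcm,K1,10.0,2.6
LAFOV,tumor_r_border,2tcm,k2,16.8,4.5
LAFOV,tumor_r_border,2tcm,k3,42.2,2.8
LAFOV,tumor_r_border,2tcm,vb,3.9,3.0
LAFOV,tumor_r_border,2tcm,Ki,29.6,2.5
LAFOV,tumor_r_center,2tcm,K1,8.1,6.7
LAFOV,tumor_r_center,2tcm,k2,14.7,9.4
LAFOV,tumor_r_center,2tcm,k3,43.6,7.3
LAFOV,tumor_r_center,2tcm,vb,9.4,7.7
LAFOV,tumor_r_center,2tcm,Ki,31.8,4.1
LAFOV,tumor_l_border,2tcm,K1,6.8,2.0
LAFOV,tumor_l_border,2tcm,k2,17.6,2.2
LAFOV,tumor_l_border,2tcm,k3,40.8,1.5
LAFOV,tumor_l_border,2tcm,vb,2.7,2.8
LAFOV,tumor_l_border,2tcm,Ki,26.8,2.3
LAFOV,tumor_l_center,2tcm,K1,7.0,5.5
LAFOV,tumor_l_center,2tcm,k2,17.2,5.6
LAFOV,tumor_l_center,2tcm,k3,38.3,4.5
LAFOV,tumor_l_center,2tcm,vb,17.9,7.6
LAFOV,tumor_l_center,2tcm,Ki,22.5,3.2
LAFOV,liver,2tcm,K1,17.7,7.2
LAFOV,liver,2tcm,k2,29.0,2.1
LAFOV,liver,2tcm,k3,45.3,1.3
LAFOV,liver,2tcm,vb,10.6,1.9
LAFOV,liver,2tcm,Ki,32.6,2.8
LAFOV,lungs,2tcm,K1,50.1,5.6
LAFOV,lungs,2tcm,k2,32.6,1.1
LAFOV,lungs,2tcm,k3,43.1,1.1
LAFOV,lungs,2tcm,vb,9.9,1.5
LAFOV,lungs,2tcm,Ki,22.4,2.4
LAFOV,bone,2tcm,K1,20.2,4.5
LAFOV,bone,2tcm,k2,17.6,1.5
LAFOV,bone,2tcm,k3,45.3,0.9
LAFOV,bone,2tcm,vb,18.9,2.5
LAFOV,bone,2tcm,Ki,30.9,2.0
LAFOV,heart,2tcm,K1,19.3,2.9
LAFOV,heart,2tcm,k2,46.8,1.2
LAFOV,heart,2tcm,k3,47.0,1.0
LAFOV,heart,2tcm,vb,7.5,1.9
LAFOV,heart,2tcm,Ki,28.5,2.3
LAFOV,spleen,2tcm,K1,32.7,7.0
LAFOV,spleen,2tcm,k2,18.3,2.6
LAFOV,spleen,2tcm,k3,40.4,2.6
LAFOV,spleen,2tcm,vb,18.5,2.5
LAFOV,spleen,2tcm,Ki,32.2,2.9
LAFOV,muscle,2tcm,K1,4.1,2.0
LAFOV,muscle,2tcm,k2,11.1,0.7
LAFOV,muscle,2tcm,k3,11.3,1.4
LAFOV,muscle,2tcm,vb,128.0,8.0
LAFOV,muscle,2tcm,Ki,21.2,2.1
LAFOV,fat,2tcm,K1,1.4,3.1
LAFOV,fat,2tcm,k2,39.9,0.6
LAFOV,fat,2tcm,k3,32.7,0.8
LAFOV,fat,2tcm,vb,43.7,4.5
LAFOV,fat,2tcm,Ki,24.6,2.1
LAFOV,tumor_r_border,patlak,Ki,6.5,1.7
LAFOV,tumor_r_border,patlak,vb,58.6,8.4
LAFOV,tumor_r_center,patlak,Ki,6.7,4.4
LAFOV,tumor_r_center,patlak,vb,51.3,15.8
LAFOV,tumor_l_border,patlak,Ki,2.8,2.0
LAFOV,tumor_l_border,patlak,vb,66.3,7.2
LAFOV,tumor_l_center,patlak,Ki,6.8,4.2
LAFOV,tumor_l_center,patlak,vb,68.8,10.5
LAFOV,liver,patlak,Ki,9.6,3.3
LAFOV,liver,patlak,vb,10.1,3.9
LAFOV,lungs,patlak,Ki,57.5,4.2
LAFOV,lungs,patlak,vb,36.9,4.7
LAFOV,bone,patlak,Ki,6.3,2.9
LAFOV,bone,patlak,vb,28.1,4.5
LAFOV,heart,patlak,Ki,3.4,1.8
LAFOV,heart,patlak,vb,26.4,4.7
LAFOV,spleen,patlak,Ki,16.2,3.8
LAFOV,spleen,patlak,vb,9.0,3.8
LAFOV,muscle,patlak,Ki,25.4,3.3
LAFOV,muscle,patlak,vb,31.5,4.6
LAFOV,fat,patlak,Ki,41.7,3.7
LAFOV,fat,patlak,vb,65.3,5.6
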