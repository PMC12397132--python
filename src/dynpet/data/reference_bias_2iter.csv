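config,structure,model,parameter,bias_pct,sd_pct
SAFOV,tumor_r_border,2tcm,K1,42.8,39.2
SAFOV,tumor_r_border,2tcm,k2,13.0,9.7
SAFOV,tumor_r_border,2tcm,k3,14.1,9.3
SAFOV,tumor_r_border,2tcm,vb,17.1,14.3
SAFOV,tumor_r_border,2tcm,Ki,41.9,4.6
SAFOV,tumor_r_center,2tcm,K1,20.5,39.7
SAFOV,tumor_r_center,2tcm,k2,23.2,17.9
SAFOV,tumor_r_center,2tcm,k3,24.4,14.4
SAFOV,tumor_r_center,2tcm,vb,77.4,35.5
SAFOV,tumor_r_center,2tcm,Ki,34.6,6.0
SAFOV,tumor_l_border,2tcm,K1,30.3,53.8
SAFOV,tumor_l_border,2tcm,k2,13.4,7.7
SAFOV,tumor_l_border,2tcm,k3,6.3,7.7
SAFOV,tumor_l_border,2tcm,vb,22.0,16.1
SAFOV,tumor_l_border,2tcm,Ki,31.3,2.9
SAFOV,tumor_l_center,2tcm,K1,22.2,81.3
SAFOV,tumor_l_center,2tcm,k2,22.0,14.6
SAFOV,tumor_l_center,2tcm,k3,10.1,9.2
SAFOV,tumor_l_center,2tcm,vb,14.1,19.5
SAFOV,tumor_l_center,2tcm,Ki,3.9,8.1
SAFOV,liver,2tcm,K1,9.1,23.0
SAFOV,liver,2tcm,k2,37.5,3.0
SAFOV,liver,2tcm,k3,52.4,3.5
SAFOV,liver,2tcm,vb,24.0,7.0
SAFOV,liver,2tcm,Ki,44.4,3.2
SAFOV,lungs,2tcm,K1,92.1,162.7
SAFOV,lungs,2tcm,k2,4.8,8.8
SAFOV,lungs,2tcm,k3,24.1,7.5
SAFOV,lungs,2tcm,vb,11.5,12.2
SAFOV,lungs,2tcm,Ki,5.2,3.7
SAFOV,bone,2tcm,K1,26.0,71.4
SAFOV,bone,2tcm,k2,7.1,8.7
SAFOV,bone,2tcm,k3,27.2,5.7
SAFOV,bone,2tcm,vb,47.6,1.9
SAFOV,bone,2tcm,Ki,44.9,2.7
SAFOV,heart,2tcm,K1,30.9,34.6
SAFOV,heart,2tcm,k2,38.7,4.9
SAFOV,heart,2tcm,k3,38.8,4.1
SAFOV,heart,2tcm,vb,5.2,14.7
SAFOV,heart,2tcm,Ki,41.4,1.8
SAFOV,spleen,2tcm,K1,26.9,30.6
SAFOV,spleen,2tcm,k2,46.8,5.6
SAFOV,spleen,2tcm,k3,59.0,4.6
SAFOV,spleen,2tcm,vb,61.4,5.7
SAFOV,spleen,2tcm,Ki,61.4,6.1
SAFOV,muscle,2tcm,K1,9.4,55.4
SAFOV,muscle,2tcm,k2,9.8,5.2
SAFOV,muscle,2tcm,k3,6.8,8.3
SAFOV,muscle,2tcm,vb,88.2,91.7
SAFOV,muscle,2tcm,Ki,23.9,2.9
SAFOV,fat,2tcm,K1,43.8,82.8
SAFOV,fat,2tcm,k2,12.5,2.6
SAFOV,fat,2tcm,k3,12.8,6.8
SAFOV,fat,2tcm,vb,55.8,42.6
SAFOV,fat,2tcm,Ki,2.5,2.1
SAFOV,tumor_r_border,patlak,Ki,29.7,9.3
SAFOV,tumor_r_border,patlak,vb,27.7,25.0
SAFOV,tumor_r_center,patlak,Ki,21.8,15.9
SAFOV,tumor_r_center,patlak,vb,20.0,28.6
SAFOV,tumor_l_border,patlak,Ki,17.8,14.7
SAFOV,tumor_l_border,patlak,vb,16.8,31.2
SAFOV,tumor_l_center,patlak,Ki,18.6,27.5
SAFOV,tumor_l_center,patlak,vb,15.7,32.2
SAFOV,liver,patlak,Ki,17.0,30.1
SAFOV,liver,patlak,vb,12.4,16.8
SAFOV,lungs,patlak,Ki,27.3,40.3
SAFOV,lungs,patlak,vb,17.7,17.8
SAFOV,bone,patlak,Ki,25.6,13.5
SAFOV,bone,patlak,vb,27.1,9.3
SAFOV,heart,patlak,Ki,26.6,13.4
SAFOV,heart,patlak,vb,6.4,20.8
SAFOV,spleen,patlak,Ki,8.6,21.0
SAFOV,spleen,patlak,vb,18.3,9.7
SAFOV,muscle,patlak,Ki,6.9,26.1
SAFOV,muscle,patlak,vb,6.4,14.7
SAFOV,fat,patlak,Ki,32.7,34.6
SAFOV,fat,patlak,vb,47.7,24.2
LAFOV,tumor_r_border,2tcm,K1,4.6,2.7
LAFOV,tumor_r_border,2tcm,k2,5.8,3.9
LAFOV,tumor_r_border,2tcm,k3,24.8,3.1
LAFOV,tumor_r_border,2tcm,vb,9.3,4.5
LAFOV,tumor_r_border,2tcm,Ki,24.3,1.9
LAFOV,tumor_r_center,2tcm,K1,9.9,7.9
LAFOV,tumor_r_center,2tcm,k2,16.1,11.6
LAFOV,tumor_r_center,2tcm,k3,25.9,8.4
LAFOV,tumor_r_center,2tcm,vb,12.9,9.0
LAFOV,tumor_r_center,2tcm,Ki,24.8,4.5
LAFOV,tumor_l_border,2tcm,K1,1.9,2.6
LAFOV,tumor_l_border,2tcm,k2,6.5,2.8
LAFOV,tumor_l_border,2tcm,k3,22.2,1.8
LAFOV,tumor_l_border,2tcm,vb,10.9,2.9
LAFOV,tumor_l_border,2tcm,Ki,20.7,1.5
LAFOV,tumor_l_center,2tcm,K1,16.9,6.3
LAFOV,tumor_l_center,2tcm,k2,12.0,6.2
LAFOV,tumor_l_center,2tcm,k3,16.5,4.6
LAFOV,tumor_l_center,2tcm,vb,7.3,6.2
LAFOV,tumor_l_center,2tcm,Ki,13.8,2.4
LAFOV,liver,2tcm,K1,11.3,5.3
LAFOV,liver,2tcm,k2,16.2,3.0
LAFOV,liver,2tcm,k3,25.1,2.2
LAFOV,liver,2tcm,vb,7.7,1.9
LAFOV,liver,2tcm,Ki,21.7,2.3
LAFOV,lungs,2tcm,K1,47.6,4.3
LAFOV,lungs,2tcm,k2,20.7,1.6
LAFOV,lungs,2tcm,k3,31.6,1.5
LAFOV,lungs,2tcm,vb,10.5,1.5
LAFOV,lungs,2tcm,Ki,24.8,1.6
LAFOV,bone,2tcm,K1,22.8,3.4
LAFOV,bone,2tcm,k2,2.1,1.5
LAFOV,bone,2tcm,k3,30.6,1.4
LAFOV,bone,2tcm,vb,19.1,2.4
LAFOV,bone,2tcm,Ki,26.0,1.5
LAFOV,heart,2tcm,K1,15.5,2.3
LAFOV,heart,2tcm,k2,30.1,1.7
LAFOV,heart,2tcm,k3,24.6,1.5
LAFOV,heart,2tcm,vb,6.0,2.3
LAFOV,heart,2tcm,Ki,20.5,1.9
LAFOV,spleen,2tcm,K1,20.3,5.4
LAFOV,spleen,2tcm,k2,10.3,3.4
LAFOV,spleen,2tcm,k3,28.2,3.1
LAFOV,spleen,2tcm,vb,12.4,1.9
LAFOV,spleen,2tcm,Ki,29.3,2.2
LAFOV,muscle,2tcm,K1,6.1,2.5
LAFOV,muscle,2tcm,k2,8.0,1.0
LAFOV,muscle,2tcm,k3,7.6,1.9
LAFOV,muscle,2tcm,vb,63.1,6.2
LAFOV,muscle,2tcm,Ki,18.4,1.5
LAFOV,fat,2tcm,K1,15.2,2.7
LAFOV,fat,2tcm,k2,16.6,0.7
LAFOV,fat,2tcm,k3,6.0,1.3
LAFOV,fat,2tcm,vb,6.8,3.5
LAFOV,fat,2tcm,Ki,14.8,1.5
LAFOV,tumor_r_border,patlak,Ki,6.9,1.5
LAFOV,tumor_r_border,patlak,vb,26.5,7.0
LAFOV,tumor_r_center,patlak,Ki,8.9,4.2
LAFOV,tumor_r_center,patlak,vb,18.0,12.6
LAFOV,tumor_l_border,patlak,Ki,3.3,1.2
LAFOV,tumor_l_border,patlak,vb,29.2,6.2
LAFOV,tumor_l_center,patlak,Ki,4.9,2.9
LAFOV,tumor_l_center,patlak,vb,26.5,8.8
LAFOV,liver,patlak,Ki,2.4,1.9
LAFOV,liver,patlak,vb,2.6,2.8
LAFOV,lungs,patlak,Ki,15.8,2.6
LAFOV,lungs,patlak,vb,10.9,3.4
LAFOV,bone,patlak,Ki,4.2,1.5
LAFOV,bone,patlak,vb,4.4,3.3
LAFOV,heart,patlak,Ki,6.5,1.2
LAFOV,heart,patlak,vb,4.6,3.4
LAFOV,spleen,patlak,Ki,3.4,2.3
LAFOV,spleen,patlak,vb,2.6,2.5
LAFOV,muscle,patlak,Ki,3.3,2.3
LAFOV,muscle,patlak,vb,7.7,3.4
LAFOV,fat,patlak,Ki,16.6,2.3
LAFOV,fat,patlak,vb,29.5,4.0
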