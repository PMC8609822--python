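participant,flex_molab,flex_mropen,ir_molab,ir_mropen,abd_molab,abd_mropen,lsqe,beta_molab,beta_mropen,abs_difference,bmi
Control (1),64.4,64.2,-2.3,-0.7,5.5,5.9,1.6,9.2,9.4,0.2,25.0
CPM+ (1),69.5,68.0,14.4,17.5,5.7,6.0,3.5,-31.6,-29.6,2.0,27.5
CPM+ (2),84.9,87.9,5.4,2.4,4.5,3.2,4.4,-1.4,-2.1,0.7,21.5
CPM- (1),76.1,79.4,23.0,20.0,2.9,1.7,4.6,3.0,2.3,0.7,26.1
CPM- (2),78.4,77.9,-8.2,-1.8,10.0,11.3,6.5,5.6,5.9,0.3,28.5
CPM- (3),84.5,81.2,8.9,17.6,5.0,5.6,9.3,-4.9,-6.7,1.8,23.2
Control (2),66.7,74.7,-0.7,-4.2,5.6,2.2,9.4,21.4,20.2,1.2,25.8
CPM+ (3),63.7,64.7,-3.7,-7.6,-4.5,4.9,10.2,-17.1,-17.3,0.1,32.6
CPM- (4),76.3,81.1,-3.7,6.2,5.7,8.9,11.5,22.6,21.5,1.1,32.8
CPM- (5),95.4,101.6,16.2,4.2,7.4,6.5,13.6,-6.8,-9.4,2.6,25.0
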