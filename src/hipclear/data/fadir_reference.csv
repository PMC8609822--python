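participant,flex_molab,flex_mropen,ir_molab,ir_mropen,abd_molab,abd_mropen,lsqe,beta_molab,beta_mropen,abs_difference,bmi
CPM- (6),89.4,88.9,7.3,7.9,8.6,8.0,0.9,-14.1,-14.1,0.0,28.0
CPM- (7),87.9,88.3,14.7,15.0,2.4,1.1,1.3,17.0,17.2,0.2,23.1
CPM- (1),86.9,88.1,38.0,37.3,1.2,-2.0,3.5,-11.1,-11.7,0.6,26.1
CPM+ (1),96.7,98.5,18.6,16.9,7.5,3.8,4.4,-36.7,-37.5,0.8,27.5
CPM- (8),90.8,93.8,19.2,17.2,6.6,3.4,4.8,-10.5,-9.9,0.6,30.3
CPM+ (4),85.5,84.9,12.4,16.5,0.9,6.9,7.2,-18.3,-18.6,0.3,19.3
CPM- (4),88.7,81.6,16.3,23.6,-14.3,-10.0,11.1,-3.5,-2.7,0.8,32.8
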