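event,day,time,det_acoustic,det_seismic,prob_acoustic,prob_seismic,prob_joint
1,2019-02-23,20:43:32,3.98,0.02,3.33,0.57,4.07
2,2019-02-23,21:01:47,4.19,0.09,3.86,0.33,11.79
3,2019-02-23,21:06:32,1.03,5.63,1.01,5.20,15.54
4,2019-02-23,21:44:12,2.24,1.48,1.76,1.35,6.69
5,2019-02-24,00:21:22,13.04,4.06,10.71,3.24,11.16
6,2019-02-24,17:42:30,0.45,0.02,0.56,0.45,14.53
7,2019-03-01,08:41:35,23.75,23.21,15.38,19.35,22.56
8,2019-03-02,10:06:50,0.05,1.63,0.27,1.47,8.01
9,2019-03-06,22:20:12,12.18,10.10,9.75,8.06,10.08
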