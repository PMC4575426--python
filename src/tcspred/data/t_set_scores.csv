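hk_id,rr_id,label,bayesian,meta
CC0248,CC0247,interacting,1.000,0.894
CC0289,CC0294,interacting,0.995,0.633
CC2755,CC2757,interacting,0.851,0.164
CC2765,CC2766,interacting,1.000,0.852
CC2932,CC2931,interacting,0.945,1.000
CenK,CenR,interacting,0.917,0.491
CckN,DivK,interacting,0.306,0.649
ChpT,CtrA,interacting,0.197,0.786
ChpT,CpdR,interacting,0.001,0.650
DivJ,CtrA,interacting,0.461,0.559
DivJ,PleD,interacting,0.385,0.723
DivJ,DivK,interacting,0.041,0.756
DivL,DivK,interacting,0.537,0.559
DivL,CtrA,interacting,0.130,0.721
PleC,DivK,interacting,0.080,0.477
PleC,PleD,interacting,0.001,0.600
ChpT,CC3477,non-interacting,0.607,0.231
ChpT,CC2757,non-interacting,0.128,0.000
ChpT,CenR,non-interacting,0.067,0.000
PleC,CtrA,non-interacting,0.002,0.022
PleC,CC3477,non-interacting,0.001,0.000
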