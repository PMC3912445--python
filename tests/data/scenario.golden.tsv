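step	length	weight	abundance	biomass
0	100.0	10400.0	1000.0	10400000.0
1	176.2	56891.98037119999	800.0	45513584.296959996
2	220.64999999999998	111723.65489609996	640.0	71503139.13350397
3	247.32	157329.82253214717	512.0	80552869.13645935
4	263.322	189886.79937824738	409.6	77777633.02533013
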