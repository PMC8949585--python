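outcome,series,visit,mean_m,sd_m
pfwd,actual,T0,114,61
pfwd,actual,T1,136,68
pfwd,actual,T2,178,82
pfwd,actual,T3,207,80
pfwd,actual,T4,235,91
pfwd,estimated,T1,151,70
pfwd,estimated,T2,184,85
pfwd,estimated,T3,205,84
pfwd,estimated,T4,220,94
6mwd,actual,T0,287,85
6mwd,actual,T1,290,83
6mwd,actual,T2,316,90
6mwd,actual,T3,315,88
6mwd,actual,T4,320,97
6mwd,estimated,T1,286,82
6mwd,estimated,T2,306,82
6mwd,estimated,T3,325,86
6mwd,estimated,T4,330,91
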