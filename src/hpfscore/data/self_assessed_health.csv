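indicator_id,jurisdiction,timepoint,category,value
self_assessed_health,ACT,T1,,63.7
self_assessed_health,ACT,T2,,60.7
self_assessed_health,NSW,T1,,63.4
self_assessed_health,NSW,T2,,65.7
self_assessed_health,NT,T1,,67.1
self_assessed_health,NT,T2,,69.1
self_assessed_health,Qld,T1,,63.7
self_assessed_health,Qld,T2,,65.8
self_assessed_health,SA,T1,,63.3
self_assessed_health,SA,T2,,60.7
self_assessed_health,Tas,T1,,61.4
self_assessed_health,Tas,T2,,63.3
self_assessed_health,Vic,T1,,62.7
self_assessed_health,Vic,T2,,66.6
self_assessed_health,WA,T1,,63.9
self_assessed_health,WA,T2,,65.1
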