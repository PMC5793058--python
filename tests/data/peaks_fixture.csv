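rt_min,mz,area,channel,condition
17.2,,53.0,radio,coral_homogenate
19.9,,47.0,radio,coral_homogenate
19.9,,88.0,radio,algal
6.9,353.2,5.0,ms,EDTA
8.5,351.2,4.0,ms,EDTA
17.2,319.2,20.0,ms,EDTA
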