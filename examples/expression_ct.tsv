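gene	sample	replicate	ct
actin	red	1	20.10
actin	red	2	20.05
actin	red	3	20.15
actin	green	1	20.08
actin	green	2	20.12
actin	green	3	20.02
myb10	red	1	24.01
myb10	red	2	24.11
myb10	red	3	23.95
myb10	green	1	26.52
myb10	green	2	26.41
myb10	green	3	26.60
chs	red	1	22.30
chs	red	2	22.41
chs	red	3	22.35
chs	green	1	24.90
chs	green	2	24.80
chs	green	3	25.01
bhlh3	red	1	27.00
bhlh3	red	2	27.10
bhlh3	red	3	26.95
bhlh3	green	1	27.05
bhlh3	green	2	26.98
bhlh3	green	3	27.12
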