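component	direction	threshold	cutoff	unit	scored
vegetables	healthy	0	200	g/day	1
fruits	healthy	0	200	g/day	1
wholegrain	healthy	0	90	g/day	1
legumes	healthy	0	10	g/day	1
nuts	healthy	0	15	g/day	1
fish	healthy	0	15	g/day	1
tea	healthy	0	450	ml/day	1
dairy	unhealthy	750	350	g/day	1
fats_oils	unhealthy	65	20	g/day	1
red_meat	unhealthy	100	45	g/day	1
processed_meat	unhealthy	50	0	g/day	1
sweet_beverages	unhealthy	250	0	ml/day	1
alcohol	unhealthy	30	10	g/day	1
salt	unhealthy	12	6	g/day	1
coffee	unhealthy	1	0	cups/day	0
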