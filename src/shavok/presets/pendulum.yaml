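# Real double-pendulum rig measurements (user supplies the data file):
# 101 delays, rank-5 truncation, forced sHAVOK with centring.
m: 101
r: 5
variant: shavok
centred: true
closed: false
dt: 0.001
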