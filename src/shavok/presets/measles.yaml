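# Weekly measles case counts (user supplies the data file): cubic-spline
# resampling to 0.0018 years, 51 delays, rank-6 forced sHAVOK.
m: 51
r: 6
variant: shavok
centred: true
closed: false
resample_dt: 0.0018
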