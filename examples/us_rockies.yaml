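# US Rocky Mountains treeline pair: subalpine spruce-fir forest below,
# alpine fellfield above. 1 spin-up year + 2 study years.
site_pair: US
n_years: 3
spinup_years: 1
seed: 1
threshold_days: 14
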