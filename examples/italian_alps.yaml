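# Italian Alps treeline pair: subalpine fir forest with suppressed beech
# understory below, alpine bunchgrass meadow above.
site_pair: IT
n_years: 3
spinup_years: 1
seed: 1
threshold_days: 14
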