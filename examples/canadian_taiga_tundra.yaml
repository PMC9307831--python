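# Western Canadian taiga-tundra pair: sparse black-spruce forest-tundra
# below the Arctic treeline, shrub tundra above.
site_pair: CA
n_years: 3
spinup_years: 1
seed: 1
threshold_days: 14
# example physics override: softer canopy extinction
# params:
#   extinction_k: 0.3
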