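# Full-pipeline demo configuration:  marsflora run --config examples/run_demo.yaml
# Simulates a landscape and 15 virtual species, fits the multi-response MARS
# model, predicts probability surfaces, thresholds them four ways, stacks
# richness/rarity maps and validates against the simulated independent survey.
out_dir: marsflora_demo_run
seed: 1
n_rows: 80
n_cols: 80
n_predictors: 3
n_species: 15
n_independent: 20
min_records: 2
max_terms: 21
richness_method: sd_band
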