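# Demo pipeline configuration: simulate -> map -> polarity -> peaks -> logo
# (cleavemap run --config examples/run.yaml --out-dir out/)
length: 10000
gc: 0.5
topology: circular
n_events: 1000
bias: gnatnc        # 'uniform', 'gnatnc', or any even-length IUPAC motif
strength: 2.0
p_nick: 0.0
f_partial: 0.0
background: 0.001   # reads per position per strand (Poisson)
reads_per_event: 1.0
threshold: 3000     # RPM; plasmid-scale preset
top_n: 50
halfwidth: 10
max_lag: 10
seed: 1
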