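"""Generate a synthetic 2x2 intergenerational count experiment.

Builds the default design (6 replicates per group, 5 in CJ), simulates
negative-binomial counts with spike-in controls and planted effects, and
prints what the truth table records.
"""

from intergen import Design, SynthConfig, generate_count_experiment

design = Design.default()
cfg = SynthConfig(n_contigs=1000, seed=7)
expt, truth = generate_count_experiment(cfg, design)

print(f"counts: {expt.counts.shape[0]} rows x {expt.counts.shape[1]} samples "
      f"({int(expt.is_spike.sum())} spike-ins)")
print("planted effect classes:", truth["effect_class"].value_counts().to_dict())
print(truth.head(3)[["effect_class", "is_hetero", "true_mean_CC", "true_mean_CJ"]])
# effect_class says which 2x2 pattern was planted per contig; the
# true_mean_* columns are the group means on the natural-log depth scale
# that the contrast engine should recover.
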