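"""Total phenolics: average technical replicates, then the 2x2 ANCOVA
with initial seed weight as covariate."""

from intergen import Design, SynthConfig, analyze_phenolics, generate_phenolics_data

design = Design.default()
cfg = SynthConfig(phen_direct_effect=2.0, phen_interaction_effect=-1.0, seed=7)
table = generate_phenolics_data(cfg, design)
print(table.head(3).round(3))

anova = analyze_phenolics(table, design)
print(anova.round(4))
# seed_weight absorbs initial-size variation; the offspring row tests the
# direct treatment effect on phenolics, parental the intergenerational
# one, and parental:offspring whether parental treatment changes the
# offspring response (inhibited inducibility shows up here).
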