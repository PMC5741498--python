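"""Filter, fit the heteroscedastic per-contig model and test the seven
a priori contrasts with pooled Storey FDR."""

from intergen import (
    Design,
    SynthConfig,
    generate_count_experiment,
    group_coverage,
    log_transform,
    partition_contigs,
    rpkm_from_experiment,
    run_contrasts,
)

design = Design.default()
cfg = SynthConfig(n_contigs=2000, frac_direct_effect=0.1, seed=7)
expt, truth = generate_count_experiment(cfg, design)

bio = expt.biological()
cov = group_coverage(bio.counts, bio.contig_length, design, read_length=cfg.read_length)
part = partition_contigs(cov, bio.contig_length, min_cov=10, min_len=500)
print("filter partition:", part.counts)
# 'analyzed' contigs pass the 10x-in-every-group depth floor and the
# 500 bp length rule; 'partial' ones fail the floor in some groups only.

expr = log_transform(rpkm_from_experiment(expt)).values.loc[sorted(part.analyzed)]
table, summary = run_contrasts(expr, design, q_threshold=0.1)
print("significant contigs per contrast and union at q <= 0.1:")
print(summary.cardinalities())
# 'direct' is the union of the two within-parental-background offspring
# contrasts; 'parental' the union of the two within-offspring parental
# contrasts; 'any' counts contigs significant in any of the seven.
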