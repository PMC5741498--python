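"""Gene-level GO enrichment with a toy ontology.

Contigs are pooled to putative genes (union of GO annotations), a
significant gene set is tested per term with a two-sided Fisher exact
test, and the significant terms are reduced to the most specific ones.
"""

import numpy as np

from intergen import fisher_enrichment, most_specific, pool_annotations

rng = np.random.default_rng(7)
genes = [f"gene_{i:03d}" for i in range(300)]
contig_to_gene = {f"contig_{i:04d}": genes[i % 300] for i in range(700)}

# toy DAG: ROOT <- A,B ; A <- A1,A2 ; B <- B1
parents = {"A": {"ROOT"}, "B": {"ROOT"}, "A1": {"A"}, "A2": {"A"}, "B1": {"B"}}
terms = list(parents) + ["ROOT"]
contig_to_go = {c: set(rng.choice(terms, 2, replace=False)) for c in contig_to_gene}

pooled = pool_annotations(contig_to_gene, contig_to_go)
print(f"{len(pooled.gene_to_go)} annotated genes ({pooled.n_unannotated} without annotation)")

# make genes carrying A1 over-represented in the significant set
carriers = [g for g, t in pooled.gene_to_go.items() if "A1" in t]
sig = set(carriers[:60]) | set(rng.choice(list(pooled.gene_to_go), 20, replace=False))
table = fisher_enrichment(sig, set(pooled.gene_to_go), pooled.gene_to_go)
print(table[["go_id", "n_significant_genes_with_term", "n_reference_genes_with_term",
             "p", "q", "significant"]].head(4).to_string(index=False))
# the enriched A1 term should top the table with a tiny p.

reduced = most_specific(set(table.loc[table["significant"], "go_id"]), parents)
print("most specific significant terms:", sorted(reduced))
# ancestors of a significant descendant are dropped: reporting 'A1'
# already implies 'A' and 'ROOT'.
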