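"""Gene-level GO enrichment.

Contigs are collapsed to putative genes; each gene carries the union of
its contigs' GO annotations. Enrichment of a significant gene set
against the annotated reference set is tested per term with a two-sided
Fisher's exact test, FDR-controlled with Benjamini-Hochberg, and
optionally reduced to the most specific significant terms using a
user-supplied parent map (no ontology download needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PooledAnnotation:
    """gene -> GO-term set, plus the genes dropped for lack of annotation."""

    gene_to_go: dict[str, frozenset]
    n_unannotated: int = 0
    unannotated: set = field(default_factory=set)


def pool_annotations(
    contig_to_gene: dict[str, str] | pd.Series,
    contig_to_go: dict[str, set],
) -> PooledAnnotation:
    """Union each gene's contig annotations; tally genes with none.

    Every contig maps to exactly one gene; contigs absent from
    ``contig_to_go`` simply contribute no terms.
    """
    if isinstance(contig_to_gene, pd.Series):
        contig_to_gene = contig_to_gene.to_dict()
    pooled: dict[str, set] = {}
    for contig, gene in contig_to_gene.items():
        pooled.setdefault(gene, set()).update(contig_to_go.get(contig, ()))
    unannotated = {g for g, terms in pooled.items() if not terms}
    return PooledAnnotation(
        gene_to_go={g: frozenset(t) for g, t in pooled.items() if t},
        n_unannotated=len(unannotated),
        unannotated=unannotated,
    )


def fisher_enrichment(
    sig_genes: set,
    ref_genes: set,
    gene_to_go: dict[str, frozenset],
    term_meta: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment per GO term.

    The universe is the annotated reference set (reference genes present
    in ``gene_to_go``); ``sig_genes`` must be a subset of ``ref_genes``.
    For each term carried by at least one universe gene the 2x2 table is
    (significant x carries-term), tested two-sided, with BH q-values
    across terms.

    ``term_meta`` (optional) is indexed by term id with columns
    ``term`` and ``namespace`` merged into the output.
    """
    sig_genes, ref_genes = set(sig_genes), set(ref_genes)
    if not sig_genes <= ref_genes:
        raise ValueError("significant gene set must be a subset of the reference set")
    universe = {g for g in ref_genes if g in gene_to_go}
    sig = sig_genes & universe
    terms: dict[str, list] = {}
    for g in universe:
        for t in gene_to_go[g]:
            terms.setdefault(t, []).append(g)
    n_ref, n_sig = len(universe), len(sig)
    rows = []
    for t in sorted(terms):
        carriers = terms[t]
        a = sum(1 for g in carriers if g in sig)  # sig with term
        b = n_sig - a
        c = len(carriers) - a  # non-sig with term
        d = n_ref - n_sig - c
        p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        rows.append(
            {
                "go_id": t,
                "n_significant_genes_with_term": a,
                "n_reference_genes_with_term": len(carriers),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] <= fdr_alpha
        if term_meta is not None:
            out = out.merge(
                term_meta.reset_index().rename(columns={term_meta.index.name or "index": "go_id"}),
                on="go_id",
                how="left",
            )
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out


def most_specific(significant_terms: set, parent_map: dict[str, set] | None) -> set:
    """Drop every significant term that has a significant descendant.

    ``parent_map`` maps a term to its (direct) parents; ancestry is the
    transitive closure. Without a parent map the input is returned
    unchanged with a warning.
    """
    if parent_map is None:
        warnings.warn("no parent map supplied; returning terms unreduced")
        return set(significant_terms)

    def ancestors(term: str) -> set:
        seen: set = set()
        stack = list(parent_map.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(parent_map.get(t, ()))
        return seen

    sig = set(significant_terms)
    with_sig_descendant: set = set()
    for t in sig:
        with_sig_descendant |= ancestors(t) & sig
    return sig - with_sig_descendant


def read_annotation_tsv(path) -> tuple[pd.Series, dict[str, set]]:
    """Read a (contig, gene, pipe-separated GO ids) TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    contig_to_gene = df.set_index("contig_id")["gene"]
    contig_to_go = {
        r["contig_id"]: {t for t in r["go_ids"].split("|") if t} for _, r in df.iterrows()
    }
    return contig_to_gene, contig_to_go


def read_parent_tsv(path) -> dict[str, set]:
    """Read a two-column (child, parent) TSV into a parent map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set] = {}
    for child, parent in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(child, set()).add(parent)
    return out
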