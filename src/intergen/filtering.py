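"""Coverage and length filtering of contigs before statistical analysis.

A contig enters the analysis only if it is long enough (>= 500 bp by
default) and shows an average per-nucleotide read depth of at least 10x
in every one of the four experimental groups. Contigs below the depth
floor everywhere are uninformative; contigs below it in some but not all
groups ("partial") may well contain treatment-driven on/off expression
but cannot support the per-group variance model, so they are reported
separately rather than tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .design import GROUPS, Design


def group_coverage(
    counts: pd.DataFrame,
    contig_length: pd.Series,
    design: Design,
    read_length: int = 91,
    pooled: bool = False,
) -> pd.DataFrame:
    """Mean per-nucleotide depth per contig per group.

    depth(contig, sample) = count * read_length / length. By default the
    group value is the mean over the group's samples; with ``pooled`` the
    group's reads are pooled first (sum of counts over samples), which
    equals the mean times n and is provided because the source phrasing
    is ambiguous between the two readings.
    """
    unknown = set(design.group_labels) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    lengths = contig_length.loc[counts.index].to_numpy(dtype=float)
    out = {}
    for g in GROUPS:
        sub = counts[design.samples_in(g)]
        agg = sub.sum(axis=1) if pooled else sub.mean(axis=1)
        out[g] = agg.to_numpy(dtype=float) * read_length / lengths
    return pd.DataFrame(out, index=counts.index)


@dataclass
class FilterPartition:
    """Disjoint, exhaustive partition of contigs by the analysis filters.

    ``analyzed``: long enough and >= min_cov depth in all groups;
    ``low_everywhere``: long enough but < min_cov in every group;
    ``partial``: long enough, < min_cov in some but not all groups;
    ``short``: below the length floor (reported separately because the
    length rule is applied before the coverage classification).
    """

    analyzed: set = field(default_factory=set)
    low_everywhere: set = field(default_factory=set)
    partial: set = field(default_factory=set)
    short: set = field(default_factory=set)
    min_cov: float = 10.0
    min_len: int = 500

    def __post_init__(self) -> None:
        sets = [self.analyzed, self.low_everywhere, self.partial, self.short]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise ValueError("partition sets overlap")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "analyzed": len(self.analyzed),
            "low_everywhere": len(self.low_everywhere),
            "partial": len(self.partial),
            "short": len(self.short),
        }


def partition_contigs(
    coverage: pd.DataFrame,
    contig_length: pd.Series,
    min_cov: float = 10.0,
    min_len: int = 500,
) -> FilterPartition:
    """Classify every contig of the coverage matrix; see :class:`FilterPartition`."""
    missing = [g for g in GROUPS if g not in coverage.columns]
    if missing:
        raise ValueError(f"coverage matrix missing groups: {missing}")
    lengths = contig_length.loc[coverage.index]
    short = set(coverage.index[lengths < min_len])
    cov = coverage[list(GROUPS)]
    ok = cov >= min_cov
    all_ok = ok.all(axis=1)
    none_ok = ~ok.any(axis=1)
    rest = coverage.index.difference(short, sort=False)
    part = FilterPartition(
        analyzed=set(rest[all_ok.loc[rest]]),
        low_everywhere=set(rest[none_ok.loc[rest]]),
        partial=set(rest[(~all_ok & ~none_ok).loc[rest]]),
        short=short,
        min_cov=min_cov,
        min_len=min_len,
    )
    assert set().union(
        part.analyzed, part.low_everywhere, part.partial, part.short
    ) == set(coverage.index)
    return part
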