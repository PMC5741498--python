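"""Normalisation and spike-in based library QC.

Expression is normalised to RPKM (reads per kilobase of contig per
million mapped reads) and log-transformed; competing normalisation
strategies are compared on the spike-in controls using expected-vs-
observed regressions and Bland-Altman (BA) agreement statistics between
within-group sample pairs. The strategy with the smallest and most
consistent BA bias wins — in the emulated study this was log(RPKM).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountExperiment, ExpressionMatrix
from .design import GROUPS, Design

DEFAULT_LOG_OFFSET = 1.0


def rpkm(
    counts: pd.DataFrame,
    contig_length: pd.Series,
    mapped_total: pd.Series,
) -> ExpressionMatrix:
    """Linear-scale RPKM: count / (length/1000) / (mapped_total/1e6)."""
    if (contig_length < 1).any():
        raise ValueError("contig lengths must be >= 1")
    if (mapped_total <= 0).any():
        raise ValueError("mapped_total must be positive for every sample")
    kb = contig_length.loc[counts.index].to_numpy(dtype=float) / 1000.0
    millions = mapped_total.loc[counts.columns].to_numpy(dtype=float) / 1e6
    values = counts.to_numpy(dtype=float) / kb[:, None] / millions[None, :]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        transform_tag="rpkm",
    )


def rpkm_from_experiment(expt: CountExperiment, include_spike_reads: bool = False) -> ExpressionMatrix:
    """RPKM over all rows of an experiment.

    ``mapped_total`` is taken from the experiment metadata; when
    ``include_spike_reads`` the spike-row column sums are added to it.
    """
    total = expt.mapped_total.astype(float)
    if include_spike_reads:
        total = total + expt.counts.loc[expt.is_spike.astype(bool)].sum(axis=0)
    return rpkm(expt.counts, expt.contig_length, total)


def log_transform(matrix: ExpressionMatrix, offset: float = DEFAULT_LOG_OFFSET) -> ExpressionMatrix:
    """Natural log of (value + offset); the default offset 1 keeps zeros finite."""
    if ((matrix.values + offset) <= 0).any().any():
        raise ValueError("value + offset must be positive everywhere")
    return ExpressionMatrix(
        values=np.log(matrix.values + offset),
        transform_tag=f"log({matrix.transform_tag}+{offset:g})",
    )


def spike_fit(observed: pd.Series, expected: pd.Series) -> dict:
    """OLS of log observed on log expected over spike rows.

    Rows with zero observed count (or zero expected) are dropped and
    counted. Returns slope, intercept, r2 and n_dropped.
    """
    expected = expected.loc[observed.index]
    keep = (observed > 0) & (expected > 0)
    n_dropped = int((~keep).sum())
    if keep.sum() < 3:
        raise ValueError("need at least 3 spike rows with nonzero observed and expected")
    x = np.log(expected[keep].to_numpy(dtype=float))
    y = np.log(observed[keep].to_numpy(dtype=float))
    if np.allclose(y, y[0]):
        # constant observed: slope 0, r2 0 by convention
        return {"slope": 0.0, "intercept": float(y[0]), "r2": 0.0, "n_dropped": n_dropped}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "n_dropped": n_dropped,
    }


def bland_altman(x: pd.Series, y: pd.Series) -> dict:
    """Bland-Altman agreement of two samples on their common rows.

    bias = mean(x - y); limits of agreement = bias +/- 1.96 sd(x - y).
    """
    common = x.index.intersection(y.index)
    d = (x.loc[common] - y.loc[common]).to_numpy(dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 common rows")
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "width": 2 * 1.96 * sd,
        "n": len(d),
    }


@dataclass
class QcReport:
    """Spike-in QC summaries.

    ``spike_fits``: per-sample expected-vs-observed regression table;
    ``ba_pairs``: per within-group sample pair BA statistics (per
    candidate normalisation when ranking); ``ranking``: candidates ordered
    best-first by (median |bias|, then median limits width).
    """

    spike_fits: pd.DataFrame | None = None
    ba_pairs: pd.DataFrame | None = None
    ranking: pd.DataFrame | None = None


def qc_spike_fits(expt: CountExperiment) -> pd.DataFrame:
    """Expected-vs-observed spike regression for every sample."""
    spikes = expt.spikes()
    rows = {}
    for s in spikes.samples:
        rows[s] = spike_fit(spikes.counts[s], spikes.spike_expected)
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def _within_group_pairs(design: Design) -> list[tuple[str, str, str]]:
    pairs = []
    for g in GROUPS:
        members = design.samples_in(g)
        if len(members) < 2:
            warnings.warn(f"group {g} has < 2 samples; skipped in BA pairing")
            continue
        pairs.extend((g, a, b) for a, b in itertools.combinations(members, 2))
    return pairs


def rank_normalizations(
    candidates: dict[str, ExpressionMatrix],
    design: Design,
    spike_mask: pd.Series,
) -> QcReport:
    """Rank candidate normalisations by spike-row BA agreement.

    For each candidate, Bland-Altman statistics are computed for every
    within-group sample pair on the spike rows; candidates are ordered by
    median |bias|, ties broken by median limits width, then stably by name.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    pairs = _within_group_pairs(design)
    records = []
    for name in sorted(candidates):
        vals = candidates[name].values
        sub = vals.loc[spike_mask.reindex(vals.index, fill_value=False).astype(bool)]
        for g, a, b in pairs:
            ba = bland_altman(sub[a], sub[b])
            records.append({"candidate": name, "group": g, "sample_a": a, "sample_b": b, **ba})
    ba_pairs = pd.DataFrame(records)
    summary = (
        ba_pairs.assign(abs_bias=lambda d: d["bias"].abs())
        .groupby("candidate")
        .agg(median_abs_bias=("abs_bias", "median"), median_width=("width", "median"))
        .reset_index()
        .sort_values(
            ["median_abs_bias", "median_width", "candidate"], kind="stable"
        )
        .reset_index(drop=True)
    )
    summary.index.name = "rank"
    return QcReport(ba_pairs=ba_pairs, ranking=summary)


# ---------------------------------------------------------------------------
# candidate normalisation strategies (log(RPKM)'s competitors)

def total_count(counts: pd.DataFrame) -> ExpressionMatrix:
    """Counts scaled so every sample sums to the mean library size."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("sample with zero total count")
    values = counts / totals * totals.mean()
    return ExpressionMatrix(values=values.astype(float), transform_tag="total_count")


def median_of_ratios(counts: pd.DataFrame) -> ExpressionMatrix:
    """DESeq-style size factors: median ratio to the geometric reference."""
    arr = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    ref = logs.mean(axis=1)
    usable = np.isfinite(ref)
    if usable.sum() < 1:
        raise ValueError("no contig expressed in every sample")
    factors = np.exp(np.median(logs[usable] - ref[usable, None], axis=0))
    values = counts / factors
    return ExpressionMatrix(values=values.astype(float), transform_tag="median_of_ratios")


def upper_quartile(counts: pd.DataFrame) -> ExpressionMatrix:
    """Counts scaled by the upper quartile of each sample's nonzero counts."""
    qs = {}
    for s in counts.columns:
        col = counts[s].to_numpy(dtype=float)
        nz = col[col > 0]
        if len(nz) == 0:
            raise ValueError(f"sample {s} has no nonzero counts")
        qs[s] = np.quantile(nz, 0.75)
    qser = pd.Series(qs)
    values = counts / qser * qser.mean()
    return ExpressionMatrix(values=values.astype(float), transform_tag="upper_quartile")


def candidate_normalizations(
    expt: CountExperiment, offset: float = DEFAULT_LOG_OFFSET
) -> dict[str, ExpressionMatrix]:
    """The shipped candidates, all on the log scale: log(RPKM),
    total-count, median-of-ratios and upper-quartile scaling."""
    return {
        "log_rpkm": log_transform(rpkm_from_experiment(expt), offset),
        "log_total_count": log_transform(total_count(expt.counts), offset),
        "log_median_of_ratios": log_transform(median_of_ratios(expt.counts), offset),
        "log_upper_quartile": log_transform(upper_quartile(expt.counts), offset),
    }
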