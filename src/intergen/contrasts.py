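"""Per-contig heteroscedastic group models and a priori contrasts.

Each contig is modelled separately as Y_ij = mu + t_i + eps_ij with the
errors of group i drawn N(0, sigma_i^2) — i.e. a cell-means model over
the four groups CC, CJ, JC, JJ with its own error variance per group.
Whether the group-specific variances are warranted is assessed per contig
by a folded F test (largest over smallest group variance) and by the BIC
difference between the homoscedastic and heteroscedastic Gaussian fits.

Seven a priori contrasts probe the 2x2 structure: the direct (offspring)
treatment effect within each parental background, the parental effect
within each offspring background, the two joint contrasts CC-JJ and
JC-CJ, and the parental x offspring interaction. Contrast tests use the
group-wise variances with Satterthwaite degrees of freedom (a Welch test
when only two groups carry weight); false discovery is controlled with
Storey q-values pooled across the full contig x contrast collection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import GROUPS, Design
from .qvalue import storey_q

#: contrast name -> coefficients over (CC, CJ, JC, JJ); all rows sum to 0
CONTRASTS: dict[str, tuple[float, float, float, float]] = {
    "direct_in_C": (1, -1, 0, 0),  # CC - CJ
    "direct_in_J": (0, 0, -1, 1),  # JJ - JC
    "parental_in_C": (1, 0, -1, 0),  # CC - JC
    "parental_in_J": (0, 1, 0, -1),  # CJ - JJ
    "joint_same": (1, 0, 0, -1),  # CC - JJ
    "joint_cross": (0, -1, 1, 0),  # JC - CJ
    "interaction": (1, -1, -1, 1),  # (CC - CJ) - (JC - JJ)
}

#: unions reported alongside the per-contrast sets
SET_UNIONS: dict[str, tuple[str, ...]] = {
    "direct": ("direct_in_C", "direct_in_J"),
    "parental": ("parental_in_C", "parental_in_J"),
    "joint": ("joint_same", "joint_cross"),
    "any": tuple(CONTRASTS),
}


@dataclass
class GroupFit:
    """Per-contig group summaries: the unit of all contrast testing."""

    contig_id: str
    means: np.ndarray  # 4-vector over GROUPS
    variances: np.ndarray  # unbiased sample variances
    ns: np.ndarray  # replicate counts
    pooled_variance: float
    hetero_F_p: float | None = None
    delta_BIC: float | None = None


@dataclass
class GroupFitMatrix:
    """Vectorised group fits for many contigs at once."""

    contig_ids: pd.Index
    means: np.ndarray  # m x 4
    variances: np.ndarray  # m x 4
    ns: np.ndarray  # length-4

    @property
    def pooled_variance(self) -> np.ndarray:
        w = self.ns - 1
        return (self.variances * w).sum(axis=1) / w.sum()

    def row(self, contig_id: str) -> GroupFit:
        i = self.contig_ids.get_loc(contig_id)
        return GroupFit(
            contig_id=contig_id,
            means=self.means[i],
            variances=self.variances[i],
            ns=self.ns,
            pooled_variance=float(self.pooled_variance[i]),
        )


def fit_groups_matrix(values: pd.DataFrame, design: Design) -> GroupFitMatrix:
    """Group means and unbiased variances for every row of an expression
    matrix. Every group needs at least two replicates."""
    cols_by_group = [design.samples_in(g) for g in GROUPS]
    ns = np.array([len(c) for c in cols_by_group])
    small = [g for g, n in zip(GROUPS, ns) if n < 2]
    if small:
        raise ValueError(f"groups with < 2 replicates are untestable: {small}")
    means = np.column_stack([values[c].mean(axis=1).to_numpy() for c in cols_by_group])
    variances = np.column_stack(
        [values[c].var(axis=1, ddof=1).to_numpy() for c in cols_by_group]
    )
    return GroupFitMatrix(contig_ids=values.index, means=means, variances=variances, ns=ns)


def fit_groups(expression_row: pd.Series, design: Design) -> GroupFit:
    """Group fit for a single contig (row)."""
    gfm = fit_groups_matrix(expression_row.to_frame().T, design)
    fit = gfm.row(gfm.contig_ids[0])
    fit.hetero_F_p = float(folded_f_matrix(gfm)[0])
    return fit


def folded_f_matrix(gfm: GroupFitMatrix) -> np.ndarray:
    """Two-sided folded F p-value per contig.

    F = max_g s2_g / min_g s2_g with df (n_argmax - 1, n_argmin - 1);
    p = min(1, 2 min(P(F' >= F), P(F' <= F))). A zero minimum variance with
    a positive maximum gives p = 0 by convention; all variances zero give
    p = 1 (no evidence either way).
    """
    v = gfm.variances
    imax = np.argmax(v, axis=1)
    imin = np.argmin(v, axis=1)
    vmax = v[np.arange(len(v)), imax]
    vmin = v[np.arange(len(v)), imin]
    dfn = gfm.ns[imax] - 1
    dfd = gfm.ns[imin] - 1
    p = np.ones(len(v))
    degenerate = (vmin == 0) & (vmax > 0)
    ok = vmin > 0
    F = np.divide(vmax, vmin, out=np.ones_like(vmax), where=ok)
    sf = stats.f.sf(F[ok], dfn[ok], dfd[ok])
    cdf = stats.f.cdf(F[ok], dfn[ok], dfd[ok])
    p[ok] = np.minimum(1.0, 2.0 * np.minimum(sf, cdf))
    p[degenerate] = 0.0
    return p


def folded_f(fit: GroupFit) -> float:
    gfm = GroupFitMatrix(
        contig_ids=pd.Index([fit.contig_id]),
        means=fit.means[None, :],
        variances=fit.variances[None, :],
        ns=fit.ns,
    )
    return float(folded_f_matrix(gfm)[0])


def bic_compare(expression_row: pd.Series, design: Design) -> float:
    """BIC_hom - BIC_het for one contig's raw values (positive favours
    the heteroscedastic model).

    Gaussian likelihoods with ML variance estimates; k_hom = 5 (four
    means, one variance), k_het = 8 (four means, four variances).
    """
    groups = [expression_row[design.samples_in(g)].to_numpy(dtype=float) for g in GROUPS]
    n_tot = sum(len(g) for g in groups)
    resid = [g - g.mean() for g in groups]
    rss = [float((r**2).sum()) for r in resid]
    sigma2_hom = max(sum(rss) / n_tot, 1e-300)
    ll_hom = -0.5 * n_tot * (np.log(2 * np.pi * sigma2_hom) + 1.0)
    ll_het = 0.0
    for r, g in zip(rss, groups):
        s2 = max(r / len(g), 1e-300)
        ll_het += -0.5 * len(g) * (np.log(2 * np.pi * s2) + 1.0)
    bic_hom = -2 * ll_hom + 5 * np.log(n_tot)
    bic_het = -2 * ll_het + 8 * np.log(n_tot)
    return float(bic_hom - bic_het)


def _contrast_arrays(
    gfm: GroupFitMatrix, coef: np.ndarray, variance_mode: str
) -> tuple[np.ndarray, ...]:
    est = gfm.means @ coef
    if variance_mode == "heteroscedastic":
        terms = (coef**2)[None, :] * gfm.variances / gfm.ns[None, :]
        se2 = terms.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((terms**2) / (gfm.ns - 1)[None, :]).sum(axis=1)
    elif variance_mode == "homoscedastic":
        se2 = gfm.pooled_variance * ((coef**2) / gfm.ns).sum()
        df = np.full(len(est), float(gfm.ns.sum() - 4))
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = np.where(
        se > 0,
        2 * stats.t.sf(np.abs(np.where(se > 0, t, 0.0)), np.maximum(df, 1e-12)),
        np.where(est == 0, 1.0, 0.0),  # degenerate: zero spread
    )
    with np.errstate(invalid="ignore"):
        t = np.where(se > 0, t, np.where(est == 0, 0.0, np.sign(est) * np.inf))
    df = np.where(se > 0, df, 0.0)
    return est, se, df, t, p


def contrast_test(
    fit: GroupFit | GroupFitMatrix,
    spec: str | np.ndarray,
    variance_mode: str = "heteroscedastic",
):
    """Test one contrast.

    ``spec`` is a contrast name from :data:`CONTRASTS` or a length-4
    coefficient vector summing to zero. For a single :class:`GroupFit`
    returns a dict (estimate, se, df, t, p); for a matrix fit returns the
    corresponding arrays.
    """
    coef = np.asarray(CONTRASTS[spec] if isinstance(spec, str) else spec, dtype=float)
    if abs(coef.sum()) > 1e-12:
        raise ValueError("contrast coefficients must sum to 0")
    single = isinstance(fit, GroupFit)
    gfm = (
        GroupFitMatrix(
            contig_ids=pd.Index([fit.contig_id]),
            means=fit.means[None, :].astype(float),
            variances=fit.variances[None, :].astype(float),
            ns=fit.ns,
        )
        if single
        else fit
    )
    est, se, df, t, p = _contrast_arrays(gfm, coef, variance_mode)
    if single:
        return {
            "estimate": float(est[0]),
            "se": float(se[0]),
            "df": float(df[0]),
            "t": float(t[0]),
            "p": float(p[0]),
        }
    return est, se, df, t, p


@dataclass
class SetSummary:
    """Significant-contig sets per contrast plus their named unions."""

    q_threshold: float
    sets: dict[str, set]

    def __post_init__(self) -> None:
        for union_name, parts in SET_UNIONS.items():
            if union_name not in self.sets:
                self.sets[union_name] = set().union(*(self.sets[p] for p in parts))

    def cardinalities(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}

    def intersection(self, a: str, b: str) -> set:
        return self.sets[a] & self.sets[b]

    def union(self, a: str, b: str) -> set:
        out = self.sets[a] | self.sets[b]
        assert len(out) == len(self.sets[a]) + len(self.sets[b]) - len(self.sets[a] & self.sets[b])
        return out

    def to_json_dict(self) -> dict:
        return {
            "q_threshold": self.q_threshold,
            "cardinalities": self.cardinalities(),
            "pairwise_intersections": {
                f"{a}&{b}": len(self.sets[a] & self.sets[b])
                for i, a in enumerate(CONTRASTS)
                for b in list(CONTRASTS)[i + 1 :]
            },
        }


def aggregate_sets(per_contrast_sets: dict[str, set], q_threshold: float = 0.1) -> SetSummary:
    """Exact set algebra over per-contrast significant sets (unions,
    intersections, cardinalities)."""
    missing = set(CONTRASTS) - set(per_contrast_sets)
    if missing:
        per_contrast_sets = {**{m: set() for m in missing}, **per_contrast_sets}
    return SetSummary(q_threshold=q_threshold, sets={k: set(v) for k, v in per_contrast_sets.items()})


def run_contrasts(
    values: pd.DataFrame,
    design: Design,
    q_threshold: float = 0.1,
    variance_mode: str = "heteroscedastic",
    fdr_pooling: str = "all",
    pi0: float | None = None,
) -> tuple[pd.DataFrame, SetSummary]:
    """Fit all contigs, test all seven contrasts, control FDR.

    ``fdr_pooling='all'`` (default) applies one Storey correction to the
    pooled contig x contrast p-value collection; ``'per_contrast'``
    corrects each contrast's family separately.

    Returns a long-format results table (one row per contig x contrast:
    estimate, se, df, t, p, q) and the :class:`SetSummary` at
    ``q_threshold``.
    """
    gfm = fit_groups_matrix(values, design)
    frames = []
    for name, coef in CONTRASTS.items():
        est, se, df, t, p = _contrast_arrays(gfm, np.asarray(coef, float), variance_mode)
        frames.append(
            pd.DataFrame(
                {
                    "contig_id": gfm.contig_ids,
                    "contrast": name,
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": t,
                    "p": p,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if fdr_pooling == "all":
        table["q"] = storey_q(table["p"].to_numpy(), pi0=pi0)
    elif fdr_pooling == "per_contrast":
        table["q"] = np.nan
        for name in CONTRASTS:
            mask = table["contrast"] == name
            table.loc[mask, "q"] = storey_q(table.loc[mask, "p"].to_numpy(), pi0=pi0)
    else:
        raise ValueError(f"unknown fdr_pooling {fdr_pooling!r}")
    sig = table[table["q"] <= q_threshold]
    sets = {name: set(sig.loc[sig["contrast"] == name, "contig_id"]) for name in CONTRASTS}
    return table, aggregate_sets(sets, q_threshold)
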