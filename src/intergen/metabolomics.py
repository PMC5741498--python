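"""Untargeted LC-MS peak-table statistics.

The pipeline mirrors a two-evidence design for calling treatment-
responsive mass signals:

1. intensities are normalised to a fixed total per sample and filtered
   to signals present (nonzero) in at least five samples;
2. multivariate structure is examined by PCA and PLS-DA, the latter
   validated with permutation tests on cross-validated Q2;
3. candidate signals are picked from OPLS-DA S-plots (covariance vs
   correlation of each signal with the predictive score);
4. each signal is tested by a gated two-way ANOVA (direct, parental and
   interaction effects on ln intensities) with BH FDR pooled across all
   three effects' p-values;
5. the high-confidence set is the intersection of the S-plot selection
   and the ANOVA-significant signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .containers import PeakTable
from .design import Design

EFFECTS = ("direct", "parental", "interaction")


# ---------------------------------------------------------------------------
# preprocessing

def normalize_total(table: PeakTable, target: float = 10_000.0) -> PeakTable:
    """Scale every sample column to sum to ``target`` (per ionisation mode)."""
    parts = []
    for mode in pd.unique(table.ion_mode):
        sub = table.select_mode(mode)
        sums = sub.intensity.sum(axis=0)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise ValueError(f"all-zero sample column(s) in mode {mode}: {bad}")
        parts.append(sub.intensity * (target / sums))
    intensity = pd.concat(parts).loc[table.signals]
    return PeakTable(intensity=intensity, mz=table.mz, rt=table.rt, ion_mode=table.ion_mode)


def presence_filter(table: PeakTable, min_samples: int = 5) -> PeakTable:
    """Keep signals with strictly positive intensity in >= min_samples samples."""
    keep = (table.intensity > 0).sum(axis=1) >= min_samples
    return PeakTable(
        intensity=table.intensity.loc[keep],
        mz=table.mz.loc[keep],
        rt=table.rt.loc[keep],
        ion_mode=table.ion_mode.loc[keep],
    )


def _ln_with_zero_policy(values: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """ln intensities; zeros replaced per signal by half its minimum
    positive value (signals with no positive value are left at 0 -> ln of
    the replacement is undefined, caller must exclude them)."""
    single = isinstance(values, pd.Series)
    df = values.to_frame().T if single else values
    arr = df.to_numpy(dtype=float).copy()
    pos = np.where(arr > 0, arr, np.inf)
    minpos = pos.min(axis=1)
    repl = np.where(np.isfinite(minpos), minpos / 2.0, np.nan)
    zero = arr <= 0
    arr[zero] = np.broadcast_to(repl[:, None], arr.shape)[zero]
    out = pd.DataFrame(np.log(arr), index=df.index, columns=df.columns)
    return out.iloc[0] if single else out


# ---------------------------------------------------------------------------
# multivariate

@dataclass
class MultivariateResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame | None = None
    explained_variance: np.ndarray | None = None
    r2: float | None = None
    q2: float | None = None
    permutation_p: float | None = None
    n_permutations: int | None = None
    extras: dict = field(default_factory=dict)


def _scale(X: np.ndarray, scaling: str) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    if scaling == "none":
        return Xc
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    if scaling == "unit_variance":
        return Xc / sd
    if scaling == "pareto":
        return Xc / np.sqrt(sd)
    raise ValueError(f"unknown scaling {scaling!r}")


def pca(
    matrix: pd.DataFrame,
    n_components: int = 2,
    scaling: str = "unit_variance",
) -> MultivariateResult:
    """PCA of a samples x signals matrix (mean-centred + chosen scaling).

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making score plots reproducible.
    """
    X = _scale(matrix.to_numpy(dtype=float), scaling)
    n_components = min(n_components, min(X.shape))
    fit = PCA(n_components=n_components, svd_solver="full").fit(X)
    load = fit.components_.T.copy()  # signals x comp
    scores = X @ load
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{i+1}" for i in range(n_components)]
    return MultivariateResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(load, index=matrix.columns, columns=comp_names),
        explained_variance=fit.explained_variance_ratio_,
    )


def _indicator(labels: pd.Series | np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if len(classes) == 2:
        return (labels == classes[1]).astype(float)[:, None]
    return np.column_stack([(labels == c).astype(float) for c in classes])


def plsda_validate(
    matrix: pd.DataFrame,
    labels,
    n_components: int = 2,
    n_perm: int = 999,
    cv_folds: int = 7,
    seed: int = 0,
    scaling: str = "unit_variance",
) -> MultivariateResult:
    """PLS-DA with k-fold cross-validated Q2 and a label-permutation test.

    R2 is the fitted fraction of indicator variance explained; Q2 the
    cross-validated analogue (1 - PRESS/TSS). The permutation p-value is
    (1 + #{perm Q2 >= observed Q2}) / (n_perm + 1).
    """
    X = _scale(matrix.to_numpy(dtype=float), scaling)
    Y = _indicator(labels)
    n = len(X)
    min_class = int(min(np.unique(np.asarray(labels), return_counts=True)[1]))
    folds = min(cv_folds, min_class, n)
    if folds < cv_folds:
        warnings.warn(f"reducing cv folds from {cv_folds} to {folds} (small class)")
    n_components = min(n_components, X.shape[1], n - 1)
    rng = np.random.default_rng(seed)

    def fit_q2(Yin: np.ndarray, fold_seed: int) -> float:
        press, tss = 0.0, 0.0
        kf = KFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        for tr, te in kf.split(X):
            pls = PLSRegression(n_components=n_components, scale=False)
            pls.fit(X[tr], Yin[tr])
            pred = pls.predict(X[te])
            press += float(((Yin[te] - pred) ** 2).sum())
            tss += float(((Yin[te] - Yin[tr].mean(axis=0)) ** 2).sum())
        return 1.0 - press / tss

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, Y)
    resid = Y - pls.predict(X)
    r2 = 1.0 - float((resid**2).sum()) / float(((Y - Y.mean(axis=0)) ** 2).sum())
    q2 = fit_q2(Y, int(rng.integers(2**31 - 1)))
    exceed = 0
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        if fit_q2(Yp, int(rng.integers(2**31 - 1))) >= q2:
            exceed += 1
    perm_p = (1 + exceed) / (n_perm + 1)
    comp_names = [f"LV{i+1}" for i in range(n_components)]
    return MultivariateResult(
        scores=pd.DataFrame(pls.x_scores_, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(pls.x_loadings_, index=matrix.columns, columns=comp_names),
        r2=r2,
        q2=q2,
        permutation_p=perm_p,
        n_permutations=n_perm,
    )


def opls_predictive_score(
    X: np.ndarray, y: np.ndarray, n_orthogonal: int = 1
) -> np.ndarray:
    """Predictive score of a single-response OPLS model.

    X must be column-centred, y centred. Orthogonal variation is deflated
    component by component before the predictive score t = X w is taken.
    """
    X = X.copy()
    w = X.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response is orthogonal to the data")
    w = w / nw
    for _ in range(n_orthogonal):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o /= n_o
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
    return X @ w


def splot_select(
    matrix: pd.DataFrame,
    labels,
    corr_threshold: float = 0.8,
    cov_quantile: float = 0.1,
    n_orthogonal: int = 1,
    scaling: str = "pareto",
) -> pd.DataFrame:
    """OPLS-DA S-plot statistics and threshold selection.

    For every signal, p(cov) = cov(t, x) and p(corr) = corr(t, x) against
    the predictive score t; selected signals satisfy
    ``|corr| >= corr_threshold`` and ``|cov|`` in the top ``cov_quantile``
    fraction. The emulated study selected signals from S-plots visually,
    so the thresholds are explicit knobs rather than a reconstruction.
    """
    if not 0 <= cov_quantile <= 1:
        raise ValueError("cov_quantile must lie in [0, 1]")
    X = _scale(matrix.to_numpy(dtype=float), scaling)
    y = _indicator(labels)
    if y.shape[1] != 1:
        raise ValueError("S-plot selection needs exactly two classes")
    y = y[:, 0] - y[:, 0].mean()
    t = opls_predictive_score(X, y, n_orthogonal=n_orthogonal)
    n = len(t)
    tc = t - t.mean()
    cov = tc @ X / (n - 1)
    sd_t = tc.std(ddof=1)
    sd_x = X.std(axis=0, ddof=1)
    denom = sd_t * sd_x
    corr = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 0)
    abscov = np.abs(cov)
    cov_floor = np.quantile(abscov, 1.0 - cov_quantile) if cov_quantile < 1 else abscov.min()
    selected = (np.abs(corr) >= corr_threshold) & (abscov >= cov_floor)
    return pd.DataFrame(
        {"cov": cov, "corr": corr, "selected": selected}, index=matrix.columns
    )


# ---------------------------------------------------------------------------
# per-signal gated ANOVA

def _design_matrices(design: Design) -> dict[str, np.ndarray]:
    a = (design.table["parental"] == "J").to_numpy(float)
    b = (design.table["offspring"] == "J").to_numpy(float)
    one = np.ones_like(a)
    return {
        "full": np.column_stack([one, a, b, a * b]),
        "mains": np.column_stack([one, a, b]),
        "no_parental": np.column_stack([one, b]),
        "no_direct": np.column_stack([one, a]),
    }


def _rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return (Y**2).sum(axis=0) - ((Q.T @ Y) ** 2).sum(axis=0)


def twoway_anova_matrix(Y: np.ndarray, design: Design) -> dict:
    """Vectorised 2x2 fixed-effects ANOVA with interaction, Type-II sums
    of squares, over the columns of Y (n_samples x n_signals).

    Returns per-effect F and p arrays plus the full-model residuals.
    Type II: each main effect is tested against the model with both main
    effects (no interaction); the interaction against the additive model;
    all with the full-model mean square error.
    """
    Y = np.asarray(Y, dtype=float)
    mats = _design_matrices(design)
    Qs = {k: np.linalg.qr(v)[0] for k, v in mats.items()}
    rss_full = _rss(Qs["full"], Y)
    rss_mains = _rss(Qs["mains"], Y)
    n = Y.shape[0]
    df_resid = n - 4
    mse = rss_full / df_resid
    ss = {
        "parental": _rss(Qs["no_parental"], Y) - rss_mains,
        "direct": _rss(Qs["no_direct"], Y) - rss_mains,
        "interaction": rss_mains - rss_full,
    }
    out: dict = {"df_resid": df_resid}
    for eff in EFFECTS:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ss[eff] / mse
        F = np.where(mse > 0, F, np.nan)
        out[f"F_{eff}"] = F
        out[f"p_{eff}"] = np.where(np.isnan(F), np.nan, stats.f.sf(F, 1, df_resid))
    out["residuals"] = Y - Qs["full"] @ (Qs["full"].T @ Y)
    out["mse"] = mse
    return out


def signal_anova(values: pd.Series, design: Design, min_nonzero: int = 3) -> dict:
    """Gated two-way ANOVA for one mass signal.

    Eligibility requires >= ``min_nonzero`` positive intensities in every
    group and residual normality (Shapiro-Wilk p > 0.05); ineligibility
    is a recorded state with a reason, never an error.
    """
    values = values.loc[design.samples]
    row: dict = {"eligible": False, "reason": ""}
    for g in ("CC", "CJ", "JC", "JJ"):
        if (values[design.samples_in(g)] > 0).sum() < min_nonzero:
            row["reason"] = f"fewer than {min_nonzero} nonzero samples in group {g}"
            return row
    ln = _ln_with_zero_policy(values).to_numpy(dtype=float)[:, None]
    res = twoway_anova_matrix(ln, design)
    for eff in EFFECTS:
        row[f"F_{eff}"] = float(res[f"F_{eff}"][0])
        row[f"p_{eff}"] = float(res[f"p_{eff}"][0])
    resid = res["residuals"][:, 0]
    if res["mse"][0] <= 0 or np.allclose(resid, resid[0]):
        row["reason"] = "degenerate (no residual variation)"
        return row
    sw_p = float(stats.shapiro(resid).pvalue)
    row["shapiro_p"] = sw_p
    if sw_p <= 0.05:
        row["reason"] = "residuals deviate from normality (Shapiro-Wilk)"
        return row
    row["eligible"] = True
    return row


# ---------------------------------------------------------------------------
# summary formatting and the full pipeline

def format_percent(count: int, total: int) -> str:
    """Percentage as printed in the summary tables: one decimal for
    values >= 10, two below (round-half-even)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count > total:
        raise ValueError("count cannot exceed total")
    v = 100.0 * count / total
    nd = 1 if v >= 10 else 2
    return f"{round(v, nd):.{nd}f}%"


def percent_value(count: int, total: int) -> float:
    """Numeric value of :func:`format_percent` (without the % sign)."""
    return float(format_percent(count, total)[:-1])


def run_peak_pipeline(
    table: PeakTable,
    design: Design,
    q_threshold: float = 0.1,
    target: float = 10_000.0,
    min_samples: int = 5,
    min_nonzero: int = 3,
    splot_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Normalise, filter, ANOVA-test and S-plot-select every signal.

    FDR (BH) is applied across the pooled p-values of all three effects of
    all eligible signals at once. ``high_confidence`` marks signals both
    S-plot-selected (for the direct or the parental comparison) and
    ANOVA-significant for at least one effect at ``q_threshold``.

    Returns (per-signal result table, summary dict with counts and
    formatted percentages per effect).
    """
    table = presence_filter(normalize_total(table, target), min_samples)
    samples = list(design.samples)
    inten = table.intensity[samples]

    # eligibility gate, vectorised where possible
    rows = []
    for sid in table.signals:
        rows.append({"signal_id": sid, **signal_anova(inten.loc[sid], design, min_nonzero)})
    results = pd.DataFrame(rows).set_index("signal_id")

    eligible = results.index[results["eligible"]]
    for eff in EFFECTS:
        results[f"q_{eff}"] = np.nan
    if len(eligible):
        pooled = np.concatenate(
            [results.loc[eligible, f"p_{eff}"].to_numpy(dtype=float) for eff in EFFECTS]
        )
        qs = multipletests(pooled, method="fdr_bh")[1]
        m = len(eligible)
        for i, eff in enumerate(EFFECTS):
            results.loc[eligible, f"q_{eff}"] = qs[i * m : (i + 1) * m]

    # S-plot candidates: union over the direct and parental comparisons,
    # per ionisation mode on the ln-transformed matrix
    splot_kwargs = splot_kwargs or {}
    selected = pd.Series(False, index=results.index)
    ln_all = _ln_with_zero_policy(inten)
    for mode in pd.unique(table.ion_mode):
        sig_ids = table.signals[table.ion_mode == mode]
        X = ln_all.loc[sig_ids].T  # samples x signals
        for factor in ("offspring", "parental"):
            labels = design.table.loc[samples, factor]
            sel = splot_select(X, labels, **splot_kwargs)
            selected.loc[sig_ids] |= sel["selected"].to_numpy()
    results["splot_selected"] = selected

    any_sig = (results[[f"q_{e}" for e in EFFECTS]] <= q_threshold).any(axis=1)
    results["high_confidence"] = results["splot_selected"] & any_sig

    n_tested = int(len(eligible))
    summary: dict = {
        "n_signals_after_filter": int(len(results)),
        "n_tested": n_tested,
        "q_threshold": q_threshold,
    }
    for eff in EFFECTS:
        n_sig = int((results.loc[eligible, f"q_{eff}"] <= q_threshold).sum())
        summary[f"n_significant_{eff}"] = n_sig
        if n_tested:
            summary[f"percent_{eff}"] = format_percent(n_sig, n_tested)
    summary["n_splot_selected"] = int(results["splot_selected"].sum())
    summary["n_high_confidence"] = int(results["high_confidence"].sum())
    return results, summary
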