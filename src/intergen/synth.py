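"""Synthetic experiments with known ground truth for the 2x2 parental x
offspring design.

Three generators emulate the three data arms of the study design:

* :func:`generate_count_experiment` — an RNA-seq contig x sample count
  table with spike-in controls, planted direct / parental / interaction
  effects on the log scale, and group-specific overdispersion
  (heteroscedasticity) in a tunable fraction of contigs;
* :func:`generate_peak_experiment` — zero-inflated log-normal LC-MS peak
  intensities in two ionisation modes with the same 2x2 effect structure;
* :func:`generate_phenolics_data` — per-plant total-phenolics assays with
  two technical replicates and a seed-weight covariate.

All randomness flows from ``config.seed`` through named
``numpy.random.SeedSequence`` child streams (one per logical quantity, in
the fixed order listed in ``_STREAMS``), so identical configs give
byte-identical outputs and adding draws to one stream never perturbs
another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import CountExperiment, PeakTable
from .design import GROUPS, Design

EFFECT_CLASSES = ("null", "direct", "parental", "interaction")

# fixed spawn order of the per-quantity random streams
_STREAMS = (
    "lengths",
    "coverage",
    "effects",
    "hetero",
    "library",
    "counts",
    "spikes",
    "peaks_negative",
    "peaks_positive",
    "phenolics",
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Count-table defaults reflect the emulated study's scale where it is
    stated: contig lengths span (200, 809, 17258) bp (assembly min /
    median / max), per-sample coverage is centred near the study's median
    of ~25 reads per nucleotide, 92 spike-ins, 44% of contigs
    heteroscedastic with the CJ group inflated, and library sizes vary
    with lognormal CV 0.2.
    """

    n_contigs: int = 2000
    n_genes: int | None = None  # default: ~1 gene per 2.3 contigs
    length_distribution: tuple[float, float, float] = (200.0, 809.0, 17258.0)
    baseline_mean: float = 25.0  # median per-nucleotide read depth
    coverage_sigma: float = 1.0  # between-contig spread of log depth
    dispersion: float = 0.05  # NB dispersion alpha (var = mu + alpha mu^2)
    frac_heteroscedastic: float = 0.44
    variance_inflation: float = 9.0  # dispersion multiplier in inflated_group
    inflated_group: str = "CJ"
    frac_direct_effect: float = 0.05
    frac_parental_effect: float = 0.02
    frac_interaction: float = 0.01
    effect_size_log: float = 1.0  # planted shift on the natural-log scale
    n_spikes: int = 92
    spike_depth: float = 0.05  # mean count at ladder concentration 1
    library_cv: float = 0.2
    read_length: int = 91
    # LC-MS arm (per-mode signal totals follow the study's detected totals)
    n_signals_negative: int = 1210
    n_signals_positive: int = 7728
    zero_inflation: float = 0.2
    peak_sigma_log: float = 0.5  # within-group sd of ln intensity
    peak_between_sigma: float = 1.5  # between-signal sd of baseline ln intensity
    peak_baseline_log: float = 4.0
    # phenolics arm (tannic-acid equivalents per g dry mass)
    phen_intercept: float = 20.0
    phen_slope: float = 5.0  # per mg seed weight
    phen_sigma: float = 1.5  # biological sd
    phen_tech_sigma: float = 0.5  # technical-replicate sd
    phen_direct_effect: float = 2.0
    phen_parental_effect: float = 0.0
    phen_interaction_effect: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.n_spikes < 0:
            raise ValueError("counts must be positive")
        fracs = (
            self.frac_direct_effect,
            self.frac_parental_effect,
            self.frac_interaction,
            self.frac_heteroscedastic,
            self.zero_inflation,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_direct_effect + self.frac_parental_effect + self.frac_interaction > 1:
            raise ValueError("effect fractions must sum to <= 1")
        if self.variance_inflation < 1:
            raise ValueError("variance_inflation must be >= 1")
        if self.inflated_group not in GROUPS:
            raise ValueError(f"unknown group {self.inflated_group!r}")
        lo, med, hi = self.length_distribution
        if not (1 <= lo <= med <= hi):
            raise ValueError("length_distribution must satisfy 1 <= min <= median <= max")

    def replace(self, **kw) -> "SynthConfig":
        d = asdict(self)
        d.update(kw)
        return SynthConfig(**d)


def _streams(config: SynthConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _draw_lengths(rng: np.random.Generator, n: int, dist) -> np.ndarray:
    """Piecewise log-uniform lengths hitting the requested min/median/max."""
    lo, med, hi = (np.log(v) for v in dist)
    u = rng.uniform(size=n)
    below = u < 0.5
    logl = np.where(below, lo + (u / 0.5) * (med - lo), med + ((u - 0.5) / 0.5) * (hi - med))
    return np.maximum(1, np.round(np.exp(logl))).astype(int)


def _assign_effects(
    rng: np.random.Generator, n: int, config: SynthConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Random effect-class labels and per-contig signs."""
    n_d = int(round(config.frac_direct_effect * n))
    n_p = int(round(config.frac_parental_effect * n))
    n_i = int(round(config.frac_interaction * n))
    classes = np.array(
        ["direct"] * n_d + ["parental"] * n_p + ["interaction"] * n_i + ["null"] * (n - n_d - n_p - n_i)
    )
    rng.shuffle(classes)
    signs = rng.choice([-1.0, 1.0], size=n)
    return classes, signs


def _group_mean_matrix(classes: np.ndarray, signs: np.ndarray, base: np.ndarray, delta: float) -> np.ndarray:
    """True per-group log-scale means (n x 4 over CC,CJ,JC,JJ).

    direct: offspring-J groups shifted; parental: parental-J groups
    shifted; interaction: the pure non-additive pattern (+,-,-,+) * delta/2.
    """
    n = len(classes)
    means = np.tile(base[:, None], (1, 4)).astype(float)
    s = signs * delta
    offspring_j = np.array([g[1] == "J" for g in GROUPS])
    parental_j = np.array([g[0] == "J" for g in GROUPS])
    inter = np.array([1.0, -1.0, -1.0, 1.0]) / 2.0
    is_d = classes == "direct"
    is_p = classes == "parental"
    is_i = classes == "interaction"
    means[is_d] += np.outer(s[is_d], offspring_j.astype(float))
    means[is_p] += np.outer(s[is_p], parental_j.astype(float))
    means[is_i] += np.outer(s[is_i], inter)
    return means


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + alpha mu^2
    (Poisson where alpha is ~0)."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def generate_count_experiment(
    config: SynthConfig, design: Design | None = None
) -> tuple[CountExperiment, pd.DataFrame]:
    """Simulate a spike-in-bearing count experiment plus its truth table.

    Returns the :class:`CountExperiment` and a truth DataFrame indexed by
    contig id with the planted effect class, per-group true log-scale
    means (``true_mean_<G>``, natural log of per-nucleotide depth),
    per-group approximate log-scale variances (``true_var_<G>``), the
    gene each contig belongs to, and the heteroscedasticity flag.
    """
    design = design or Design.default()
    sizes = design.group_sizes
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"groups with < 2 replicates (variance inestimable): {small}")

    rngs = _streams(config)
    n = config.n_contigs
    contig_ids = pd.Index([f"contig_{i:06d}" for i in range(n)], name="contig_id")

    lengths = _draw_lengths(rngs["lengths"], n, config.length_distribution)
    base_logcov = rngs["coverage"].normal(np.log(config.baseline_mean), config.coverage_sigma, size=n)
    classes, signs = _assign_effects(rngs["effects"], n, config)
    true_means = _group_mean_matrix(classes, signs, base_logcov, config.effect_size_log)

    hetero = rngs["hetero"].uniform(size=n) < config.frac_heteroscedastic
    alpha = np.full((n, 4), config.dispersion)
    g_infl = GROUPS.index(config.inflated_group)
    alpha[hetero, g_infl] *= config.variance_inflation

    lib = rngs["library"].lognormal(
        mean=-0.5 * np.log(1 + config.library_cv**2),
        sigma=np.sqrt(np.log(1 + config.library_cv**2)),
        size=len(design.samples),
    )
    lib = pd.Series(lib, index=design.samples)

    counts = pd.DataFrame(0, index=contig_ids, columns=pd.Index(design.samples, name="sample_id"))
    rng_counts = rngs["counts"]
    scale = lengths / config.read_length  # depth -> expected read count
    for gi, g in enumerate(GROUPS):
        mu_g = np.exp(true_means[:, gi]) * scale
        for s in design.samples_in(g):
            counts[s] = _nb_draw(rng_counts, mu_g * lib[s], alpha[:, gi])

    # spike-ins: deterministic 2-fold ladder, 23 levels x 4 entries,
    # independent of experimental group
    m = config.n_spikes
    spike_ids = pd.Index([f"spike_{j:03d}" for j in range(m)], name="contig_id")
    conc = 2.0 ** (np.arange(m) // 4)
    spike_len = np.round(rngs["spikes"].uniform(250, 2000, size=m)).astype(int)
    spike_counts = pd.DataFrame(0, index=spike_ids, columns=counts.columns)
    for s in design.samples:
        spike_counts[s] = _nb_draw(rngs["spikes"], conc * config.spike_depth * lib[s], 0.005)

    all_counts = pd.concat([counts, spike_counts])
    all_len = pd.Series(np.concatenate([lengths, spike_len]), index=all_counts.index)
    is_spike = pd.Series(
        np.concatenate([np.zeros(n, bool), np.ones(m, bool)]), index=all_counts.index
    )
    expected = pd.Series(np.concatenate([np.full(n, np.nan), conc]), index=all_counts.index)
    mapped_total = counts.sum(axis=0).astype(float)

    expt = CountExperiment(
        counts=all_counts,
        contig_length=all_len,
        mapped_total=mapped_total,
        is_spike=is_spike,
        spike_expected=expected,
    )

    n_genes = config.n_genes or max(1, int(round(n / 2.3)))
    gene = [f"gene_{i % n_genes:05d}" for i in range(n)]
    mu_counts = np.exp(true_means) * scale[:, None]
    true_var = np.log1p(1.0 / np.maximum(mu_counts, 1e-9) + alpha)
    truth = pd.DataFrame(
        {
            "effect_class": classes,
            "gene": gene,
            "is_hetero": hetero,
            **{f"true_mean_{g}": true_means[:, i] for i, g in enumerate(GROUPS)},
            **{f"true_var_{g}": true_var[:, i] for i, g in enumerate(GROUPS)},
        },
        index=contig_ids,
    )
    return expt, truth


def generate_peak_experiment(
    config: SynthConfig, design: Design | None = None
) -> tuple[PeakTable, pd.DataFrame]:
    """Simulate a two-mode LC-MS peak table plus its truth table.

    Intensities are log-normal around planted per-group means; a
    ``zero_inflation`` fraction of cells is set to zero (signal not
    detected in that sample), exercising presence filters downstream.
    """
    design = design or Design.default()
    rngs = _streams(config)
    samples = pd.Index(design.samples, name="sample_id")
    groups = design.group_labels

    frames, truths = [], []
    for mode, n_sig in (
        ("negative", config.n_signals_negative),
        ("positive", config.n_signals_positive),
    ):
        rng = rngs[f"peaks_{mode}"]
        ids = pd.Index([f"{mode[:3]}_{i:05d}" for i in range(n_sig)], name="signal_id")
        base = rng.normal(config.peak_baseline_log, config.peak_between_sigma, size=n_sig)
        classes, signs = _assign_effects(rng, n_sig, config)
        means = _group_mean_matrix(classes, signs, base, config.effect_size_log)
        gidx = np.array([GROUPS.index(g) for g in groups])
        ln_int = rng.normal(means[:, gidx], config.peak_sigma_log)
        inten = np.exp(ln_int)
        inten[rng.uniform(size=inten.shape) < config.zero_inflation] = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "mz": rng.uniform(100, 1500, size=n_sig),
                    "rt": rng.uniform(0.5, 15.0, size=n_sig),
                    "mode": mode,
                },
                index=ids,
            ).join(pd.DataFrame(inten, index=ids, columns=samples))
        )
        truths.append(
            pd.DataFrame(
                {
                    "effect_class": classes,
                    "mode": mode,
                    **{f"true_mean_{g}": means[:, i] for i, g in enumerate(GROUPS)},
                },
                index=ids,
            )
        )
    df = pd.concat(frames)
    table = PeakTable(
        intensity=df[samples],
        mz=df["mz"],
        rt=df["rt"],
        ion_mode=df["mode"],
    )
    return table, pd.concat(truths)


def generate_phenolics_data(config: SynthConfig, design: Design | None = None) -> pd.DataFrame:
    """Simulate per-plant total phenolics with two technical replicates.

    The per-plant expectation is linear in seed weight plus 2x2 group
    effects: ``phen_direct_effect`` for offspring-J groups,
    ``phen_parental_effect`` for parental-J groups, and
    ``phen_interaction_effect`` added to JJ only.
    """
    design = design or Design.default()
    rng = _streams(config)["phenolics"]
    t = design.table
    n = len(t)
    seed_w = rng.lognormal(mean=np.log(0.6), sigma=0.25, size=n)  # mg
    eff = (
        config.phen_direct_effect * (t["offspring"] == "J").to_numpy()
        + config.phen_parental_effect * (t["parental"] == "J").to_numpy()
        + config.phen_interaction_effect * (t["group"] == "JJ").to_numpy()
    )
    value = (
        config.phen_intercept
        + config.phen_slope * seed_w
        + eff
        + rng.normal(0, config.phen_sigma, size=n)
    )
    rep1 = value + rng.normal(0, config.phen_tech_sigma, size=n)
    rep2 = value + rng.normal(0, config.phen_tech_sigma, size=n)
    out = pd.DataFrame(
        {
            "group": t["group"],
            "parental": t["parental"],
            "offspring": t["offspring"],
            "seed_weight": seed_w,
            "rep1": np.maximum(rep1, 0.0),
            "rep2": np.maximum(rep2, 0.0),
        },
        index=t.index.rename("plant_id"),
    )
    return out
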