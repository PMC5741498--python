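"""The heteroscedastic contrast engine: group fits, folded F, BIC model
comparison, Satterthwaite contrasts, Storey FDR and set algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special, stats

from intergen import (
    CONTRASTS,
    aggregate_sets,
    bic_compare,
    contrast_test,
    fit_groups,
    fit_groups_matrix,
    folded_f,
    folded_f_matrix,
    run_contrasts,
    storey_q,
)
from intergen.design import GROUPS

from conftest import gaussian_matrix


def _fit_from_lists(design, groups: dict):
    row = {}
    for g, vals in groups.items():
        for s, v in zip(design.samples_in(g), vals):
            row[s] = float(v)
    return fit_groups(pd.Series(row), design)


@pytest.fixture(scope="module")
def balanced_design():
    from intergen import Design

    return Design.default({g: 3 for g in GROUPS})


class TestFitGroups:
    def test_constant_observations(self, balanced_design):
        fit = _fit_from_lists(balanced_design, {g: [4.0, 4.0, 4.0] for g in GROUPS})
        assert np.allclose(fit.means, 4.0)
        assert np.allclose(fit.variances, 0.0)

    def test_hand_computed_means_and_variances(self, balanced_design):
        fit = _fit_from_lists(
            balanced_design,
            {"CC": [1, 2, 3], "CJ": [4, 5, 6], "JC": [7, 8, 9], "JJ": [10, 11, 12]},
        )
        assert np.allclose(fit.means, [2, 5, 8, 11])
        assert np.allclose(fit.variances, 1.0)
        assert fit.pooled_variance == pytest.approx(1.0)

    def test_within_group_permutation_invariance(self, balanced_design):
        a = _fit_from_lists(balanced_design, {"CC": [1, 2, 3], "CJ": [4, 5, 6], "JC": [7, 8, 9], "JJ": [10, 11, 12]})
        b = _fit_from_lists(balanced_design, {"CC": [3, 1, 2], "CJ": [6, 4, 5], "JC": [9, 7, 8], "JJ": [12, 10, 11]})
        assert np.allclose(a.means, b.means)
        assert np.allclose(a.variances, b.variances)

    def test_group_below_two_replicates_rejected(self):
        from intergen import Design

        d = Design.default({"CC": 2, "CJ": 2, "JC": 2, "JJ": 1})
        vals = pd.DataFrame(np.ones((1, 7)), columns=d.samples)
        with pytest.raises(ValueError, match="untestable"):
            fit_groups_matrix(vals, d)


def _f_density_p_upper(F, dfn, dfd):
    """Independent oracle: upper-tail F probability by numerical
    integration of the density written from the definition."""

    def dens(x):
        c = special.gamma((dfn + dfd) / 2) / (special.gamma(dfn / 2) * special.gamma(dfd / 2))
        c *= (dfn / dfd) ** (dfn / 2)
        return c * x ** (dfn / 2 - 1) * (1 + dfn * x / dfd) ** (-(dfn + dfd) / 2)

    val, _ = integrate.quad(dens, F, np.inf)
    return val


class TestFoldedF:
    def test_equal_variances_give_p_one(self, design):
        fit = _fit_from_lists(
            design, {g: list(range(len(design.samples_in(g)))) for g in GROUPS}
        )
        fit.variances = np.array([2.0, 2.0, 2.0, 2.0])
        assert folded_f(fit) == pytest.approx(1.0)

    def test_variance_ratio_four_against_integration_oracle(self):
        """s2 = (1,1,1,4), n = 6 everywhere: F = 4 on (5, 5) df; the
        two-sided folded p is checked against numerical integration of
        the F density."""
        from intergen import Design, GroupFit

        fit = GroupFit(
            contig_id="c",
            means=np.zeros(4),
            variances=np.array([1.0, 1.0, 1.0, 4.0]),
            ns=np.array([6, 6, 6, 6]),
            pooled_variance=1.75,
        )
        p = folded_f(fit)
        upper = _f_density_p_upper(4.0, 5, 5)
        assert p == pytest.approx(min(1.0, 2 * min(upper, 1 - upper)), rel=1e-8)

    def test_invariant_to_group_relabelling(self):
        from intergen import GroupFit

        base = np.array([0.5, 1.0, 2.0, 8.0])
        ns = np.array([6, 6, 6, 6])
        ps = []
        for perm in ([0, 1, 2, 3], [3, 2, 1, 0], [1, 3, 0, 2]):
            fit = GroupFit("c", np.zeros(4), base[perm], ns, float(base.mean()))
            ps.append(folded_f(fit))
        assert np.allclose(ps, ps[0])

    def test_zero_min_variance_convention(self):
        from intergen import GroupFit

        fit = GroupFit("c", np.zeros(4), np.array([0.0, 1.0, 1.0, 1.0]), np.array([6] * 4), 0.75)
        assert folded_f(fit) == 0.0


class TestBicCompare:
    def test_location_invariance(self, design, rng):
        row = pd.Series(rng.normal(0, 1, len(design.samples)), index=design.samples)
        assert bic_compare(row, design) == pytest.approx(bic_compare(row + 100.0, design))

    def test_homoscedastic_truth_favours_common_variance_on_average(self, design):
        r = np.random.default_rng(5)
        deltas = [
            bic_compare(pd.Series(r.normal(0, 1, 23), index=design.samples), design)
            for _ in range(300)
        ]
        assert np.mean(np.array(deltas) < 0) > 0.5

    def test_strong_heteroscedasticity_favoured(self):
        """One group at 25x the variance of the rest (n = 6 per group)
        wins the BIC comparison in at least 95% of 500 simulations."""
        from intergen import Design

        d = Design.default({g: 6 for g in GROUPS})
        r = np.random.default_rng(6)
        wins = 0
        cj = d.samples_in("CJ")
        for _ in range(500):
            row = pd.Series(r.normal(0, 1, 24), index=d.samples)
            row[cj] = r.normal(0, 5, len(cj))
            if bic_compare(row, d) > 0:
                wins += 1
        assert wins / 500 >= 0.95


class TestContrastTest:
    def test_identical_group_means_give_p_one(self, balanced_design):
        fit = _fit_from_lists(
            balanced_design, {g: [1.0, 2.0, 3.0] for g in GROUPS}
        )
        for name in CONTRASTS:
            assert contrast_test(fit, name)["p"] == pytest.approx(1.0)

    def test_hand_welch_two_group_case(self, balanced_design):
        """CC = (10,12,14), CJ = (20,22,24): estimate -10, se^2 = 8/3,
        Satterthwaite df = 4 — the textbook Welch computation."""
        fit = _fit_from_lists(
            balanced_design,
            {"CC": [10, 12, 14], "CJ": [20, 22, 24], "JC": [0, 0, 0], "JJ": [0, 0, 0]},
        )
        res = contrast_test(fit, "direct_in_C")
        assert res["estimate"] == pytest.approx(-10.0)
        assert res["se"] == pytest.approx(np.sqrt(8 / 3))
        assert res["df"] == pytest.approx(4.0)
        assert abs(res["t"]) == pytest.approx(10 / np.sqrt(8 / 3))
        # independent oracle
        t_ref, p_ref = stats.ttest_ind([10, 12, 14], [20, 22, 24], equal_var=False)
        assert res["t"] == pytest.approx(t_ref) and res["p"] == pytest.approx(p_ref)

    def test_interaction_vanishes_for_additive_means(self):
        from intergen import GroupFit

        r = np.random.default_rng(7)
        for _ in range(20):
            a, b, d = r.normal(size=3)
            fit = GroupFit(
                "c", np.array([a, a + d, b, b + d]), np.ones(4), np.array([6, 5, 6, 6]), 1.0
            )
            assert contrast_test(fit, "interaction")["estimate"] == pytest.approx(0.0, abs=1e-12)

    def test_welch_equivalence_on_fuzzed_two_group_contrasts(self, design):
        """For any two-group contrast the Satterthwaite test agrees with
        an independent unequal-variance two-sample t to 1e-10."""
        r = np.random.default_rng(8)
        for _ in range(200):
            row = pd.Series(r.normal(0, r.uniform(0.5, 3), 23), index=design.samples)
            fit = fit_groups_matrix(row.to_frame().T, design)
            res = contrast_test(fit.row(fit.contig_ids[0]), "direct_in_C")
            a = row[design.samples_in("CC")]
            b = row[design.samples_in("CJ")]
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
            assert res["t"] == pytest.approx(t_ref, abs=1e-10)
            assert res["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_reduces_to_classical_t_with_equal_variances_and_n(self, design):
        """When the two groups have identical sample variances and sizes
        the heteroscedastic test equals the pooled two-sample t."""
        r = np.random.default_rng(9)
        for _ in range(50):
            a = r.normal(0, 1, 6)
            b = r.normal(1, 1, 6)
            b = (b - b.mean()) / b.std(ddof=1) * a.std(ddof=1) + b.mean()  # match variances
            row = {}
            for s, v in zip(design.samples_in("CC"), a):
                row[s] = v
            for s, v in zip(design.samples_in("JC"), b):
                row[s] = v
            for g in ("CJ", "JJ"):
                for i, s in enumerate(design.samples_in(g)):
                    row[s] = float(i)
            fit = fit_groups_matrix(pd.Series(row).to_frame().T, design)
            res = contrast_test(fit.row(fit.contig_ids[0]), "parental_in_C")
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert res["t"] == pytest.approx(t_ref, abs=1e-10)
            assert res["df"] == pytest.approx(10.0, abs=1e-8)
            assert res["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_zero_spread(self):
        from intergen import GroupFit

        ns = np.array([6, 5, 6, 6])
        fit = GroupFit("c", np.array([1.0, 0.0, 0.0, 0.0]), np.zeros(4), ns, 0.0)
        assert contrast_test(fit, "direct_in_C")["p"] == 0.0
        fit0 = GroupFit("c", np.zeros(4), np.zeros(4), ns, 0.0)
        assert contrast_test(fit0, "direct_in_C")["p"] == 1.0

    def test_coefficients_must_sum_to_zero(self, design, rng):
        row = pd.Series(rng.normal(size=23), index=design.samples)
        fit = fit_groups_matrix(row.to_frame().T, design)
        with pytest.raises(ValueError, match="sum to 0"):
            contrast_test(fit.row(fit.contig_ids[0]), np.array([1.0, 0, 0, 0]))

    def test_type_one_error_heteroscedastic_within_band(self, design):
        """Under a 1:9 variance ratio the Satterthwaite contrast holds its
        nominal 5% level while the pooled-variance test does not
        (unbalanced n) — the rationale for group-wise variances."""
        group_sd = {"CC": 1.0, "CJ": 3.0, "JC": 1.0, "JJ": 1.0}
        vals = gaussian_matrix(design, 10_000, seed=42, group_sd=group_sd)
        gfm = fit_groups_matrix(vals, design)
        _, _, _, _, p_het = contrast_test(gfm, "direct_in_C")
        alpha_het = float((p_het < 0.05).mean())
        assert 0.035 <= alpha_het <= 0.065
        _, _, _, _, p_hom = contrast_test(gfm, "direct_in_C", variance_mode="homoscedastic")
        alpha_hom = float((p_hom < 0.05).mean())
        assert alpha_hom > 0.065 or alpha_hom < 0.035


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Independent step-up Benjamini-Hochberg implementation."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


class TestStoreyQ:
    def test_all_ones_stay_one(self):
        assert np.allclose(storey_q(np.ones(10)), 1.0)

    def test_pinned_pi0_equals_bh_oracle(self, rng):
        p = np.concatenate([rng.uniform(0, 1, 400), rng.uniform(0, 0.01, 100)])
        assert np.allclose(storey_q(p, pi0=1.0), _bh_oracle(p), atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0, 1, 500)
        q = storey_q(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_q_never_exceeds_one(self, rng):
        assert (storey_q(rng.uniform(0, 1, 200)) <= 1.0).all()

    def test_empty_input_gives_empty_output(self):
        assert storey_q(np.array([])).size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            storey_q(np.array([0.5, 1.5]))

    def test_pi0_near_one_for_uniform_p(self, rng):
        p = rng.uniform(0, 1, 20_000)
        from intergen import estimate_pi0

        assert estimate_pi0(p) > 0.9


class TestSetAlgebra:
    def test_direct_union_count_with_overlap(self):
        """Sets of 149 and 440 with a 38-contig overlap give 551 unique
        direct-effect contigs."""
        a = {f"x{i}" for i in range(149)}
        b = {f"x{i}" for i in range(111, 551)}  # 440 elements, 38 shared
        assert len(a & b) == 38 and len(b) == 440
        summary = aggregate_sets({"direct_in_C": a, "direct_in_J": b})
        assert summary.cardinalities()["direct"] == 551

    def test_disjoint_parental_sets(self):
        a = {f"p{i}" for i in range(18)}
        b = {f"q{i}" for i in range(74)}
        summary = aggregate_sets({"parental_in_J": a, "parental_in_C": b})
        assert summary.cardinalities()["parental"] == 92

    def test_subset_union_is_superset(self):
        a = {"x", "y"}
        b = {"x", "y", "z"}
        summary = aggregate_sets({"direct_in_C": a, "direct_in_J": b})
        assert summary.sets["direct"] == b

    def test_inclusion_exclusion_holds(self, rng):
        ids = [f"c{i}" for i in range(200)]
        a = set(rng.choice(ids, 80, replace=False))
        b = set(rng.choice(ids, 60, replace=False))
        s = aggregate_sets({"direct_in_C": a, "direct_in_J": b})
        assert len(s.sets["direct"]) == len(a) + len(b) - len(a & b)


class TestRunContrasts:
    def test_null_simulation_yields_almost_no_discoveries(self, design):
        vals = gaussian_matrix(design, 5000, seed=3)
        _, summary = run_contrasts(vals, design, q_threshold=0.1)
        assert len(summary.sets["any"]) <= 5

    def test_planted_direct_effects_leak_little_into_parental_sets(self, design):
        vals = gaussian_matrix(design, 2000, seed=13)
        affected = vals.index[:200]
        j_offspring = [s for s in design.samples if design.group_of(s)[1] == "J"]
        vals.loc[affected, j_offspring] += 3.0
        _, summary = run_contrasts(vals, design)
        assert len(summary.sets["direct"] & set(affected)) >= 150
        # parental contrasts compare groups with the same offspring letter
        assert len(summary.sets["parental"]) <= 0.15 * max(1, len(summary.sets["direct"]))

    def test_per_contrast_pooling_mode(self, design):
        vals = gaussian_matrix(design, 100, seed=14)
        table, _ = run_contrasts(vals, design, fdr_pooling="per_contrast")
        assert table["q"].notna().all()

    def test_result_table_shape_and_q_monotonicity(self, design):
        vals = gaussian_matrix(design, 50, seed=15)
        table, _ = run_contrasts(vals, design)
        assert len(table) == 50 * len(CONTRASTS)
        srt = table.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()
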