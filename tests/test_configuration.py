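import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest

import shoalmix as sm
from shoalmix.errors import DomainError, FittingError


def make_classifications(spec):
    """spec: list of (origin_config, shoal_type, size) tuples."""
    return [
        sm.ShoalClassification(f"s{i}", cfg, st, size)
        for i, (cfg, st, size) in enumerate(spec)
    ]


class TestClassification:
    def test_single_native_species(self, catalog, shoal):
        c = sm.classify_shoal(shoal(counts={"sp1": 5}), catalog)
        assert (c.origin_config, c.shoal_type) == ("native_only", "mono_specific")
        assert c.shoal_size == 5

    def test_two_range_extenders(self, catalog, shoal):
        c = sm.classify_shoal(shoal(counts={"sp3": 2, "sp4": 3}), catalog)
        assert (c.origin_config, c.shoal_type) == (
            "range_extending_only",
            "multi_specific",
        )

    def test_both_origins(self, catalog, shoal):
        c = sm.classify_shoal(shoal(counts={"sp1": 4, "sp4": 6}), catalog)
        assert (c.origin_config, c.shoal_type) == ("mixed_origin", "multi_specific")

    def test_classification_partitions_any_dataset(self, catalog):
        recs = sm.generate_shoal_observations(
            sm.default_assembly_params(), 200, seed=1
        )
        cls = sm.classify_all(recs, sm.STUDY_CATALOG)
        assert len(cls) == len(recs)
        freq = sm.configuration_frequencies(cls)
        assert freq.by_origin["count"].sum() == 200
        assert freq.by_origin["percent"].sum() == pytest.approx(100.0)
        assert freq.by_origin_type["count"].sum() == 200

    def test_uniform_frequencies(self):
        cls = make_classifications(
            [
                ("native_only", "mono_specific", 4),
                ("range_extending_only", "mono_specific", 5),
                ("mixed_origin", "multi_specific", 6),
            ]
        )
        freq = sm.configuration_frequencies(cls).by_origin
        assert list(freq.percent) == pytest.approx([100 / 3] * 3)

    def test_order_invariance(self):
        spec = [
            ("native_only", "mono_specific", 4),
            ("mixed_origin", "multi_specific", 8),
            ("native_only", "multi_specific", 3),
        ]
        f1 = sm.configuration_frequencies(make_classifications(spec)).by_origin
        f2 = sm.configuration_frequencies(make_classifications(spec[::-1])).by_origin
        assert f1.equals(f2)


def enumeration_fisher_p(a, b, c, d):
    """Brute-force oracle: enumerate every table with the observed margins,
    compute each probability in exact rational arithmetic, and sum those no
    larger than the observed table's."""
    R, C, N = a + b, a + c, a + b + c + d
    total = comb(N, C)
    probs = {}
    for k in range(max(0, C - (N - R)), min(R, C) + 1):
        probs[k] = Fraction(comb(R, k) * comb(N - R, C - k), total)
    p = sum(v for v in probs.values() if v <= probs[a])
    return float(p)


class TestFisherExact:
    def test_perfect_balance(self):
        res = sm.fisher_exact_2x2(sm.ContingencyTable2x2(5, 5, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_diagonal_matches_enumeration(self):
        res = sm.fisher_exact_2x2(sm.ContingencyTable2x2(1, 9, 9, 1))
        assert res.p_value == pytest.approx(
            enumeration_fisher_p(1, 9, 9, 1), abs=1e-12
        )
        assert res.odds_ratio < 1

    def test_conditional_mle_matches_r(self):
        # R: fisher.test(matrix(c(3,1,1,3),2,2)) -> OR 6.408309, p 0.4857143
        res = sm.fisher_exact_2x2(sm.ContingencyTable2x2(3, 1, 1, 3))
        assert res.odds_ratio == pytest.approx(6.408309, abs=1e-4)
        assert res.p_value == pytest.approx(0.4857143, abs=1e-7)

    def test_zero_margin_degenerate_but_p_returned(self):
        res = sm.fisher_exact_2x2(sm.ContingencyTable2x2(0, 0, 5, 5))
        assert res.degenerate and res.odds_ratio is None
        assert res.p_value == pytest.approx(1.0)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        from scipy import stats

        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b + c + d == 0:
                continue
            table = sm.ContingencyTable2x2(int(a), int(b), int(c), int(d))
            _, p_scipy = stats.fisher_exact([[a, b], [c, d]])
            assert sm.fisher_exact_2x2(table).p_value == pytest.approx(
                p_scipy, abs=1e-9
            )


class TestChiSquare:
    def test_hand_computed_statistic(self):
        res = sm.chi_square_2x2(sm.ContingencyTable2x2(10, 20, 20, 10))
        assert res.statistic == pytest.approx(100 / 15)
        assert res.df == 1

    def test_independence_gives_zero(self):
        res = sm.chi_square_2x2(sm.ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = sm.ContingencyTable2x2(3, 11, 8, 2)
        tt = sm.ContingencyTable2x2(3, 8, 11, 2)
        assert sm.chi_square_2x2(t).statistic == pytest.approx(
            sm.chi_square_2x2(tt).statistic
        )

    def test_matches_scipy(self):
        from scipy import stats

        t = sm.ContingencyTable2x2(7, 66, 20, 81)
        res = sm.chi_square_2x2(t)
        chi2, p, dof, _ = stats.chi2_contingency(t.as_array(), correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(p)
        res_y = sm.chi_square_2x2(t, yates=True)
        chi2_y, *_ = stats.chi2_contingency(t.as_array(), correction=True)
        assert res_y.statistic == pytest.approx(chi2_y)

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            sm.chi_square_2x2(sm.ContingencyTable2x2(0, 0, 5, 5))


class TestOriginTypeTable:
    def test_counts_by_group(self):
        cls = make_classifications(
            [
                ("native_only", "mono_specific", 5),
                ("native_only", "multi_specific", 4),
                ("range_extending_only", "multi_specific", 6),
                ("range_extending_only", "multi_specific", 7),
                ("range_extending_only", "mono_specific", 3),
                ("mixed_origin", "multi_specific", 9),  # excluded from the table
            ]
        )
        t = sm.build_origin_type_table(cls)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 2, 1)


class TestShoalSizeModel:
    @staticmethod
    def simulate(rng, log_means, n_per_group=100, sd=0.5):
        spec = []
        configs = ["native_only", "range_extending_only", "mixed_origin"]
        for cfg, lm in zip(configs, log_means):
            sizes = np.maximum(
                np.rint(np.exp(rng.normal(lm, sd, n_per_group))), 2
            ).astype(int)
            st = "multi_specific" if cfg == "mixed_origin" else "mono_specific"
            spec += [(cfg, st, int(s)) for s in sizes]
        return make_classifications(spec)

    def test_separated_group_gets_own_letter(self):
        """Groups simulated at log-means (1, 2, 2): the small group differs
        from both others and the letter display reads a/b/b."""
        rng = np.random.default_rng(10)
        cls = self.simulate(rng, [1.0, 2.0, 2.0])
        fit = sm.fit_shoal_size_model(cls)
        small = "native_only"
        for _, row in fit.contrasts.iterrows():
            involves_small = small in (row.group_1, row.group_2)
            assert (row.p_tukey < 0.001) == involves_small or not involves_small
            if involves_small:
                assert row.p_tukey < 0.001
        letters = fit.letters
        assert letters["mixed_origin"] == letters["range_extending_only"]
        assert letters[small] != letters["mixed_origin"]

    def test_tukey_p_never_below_unadjusted(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            cls = self.simulate(rng, rng.normal(1.5, 0.3, 3), n_per_group=20)
            fit = sm.fit_shoal_size_model(cls)
            assert (fit.contrasts.p_tukey >= fit.contrasts.p_unadjusted - 1e-12).all()

    def test_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(12)
        cls = self.simulate(rng, [1.2, 1.5, 1.6], n_per_group=40)
        fit = sm.fit_shoal_size_model(cls)
        y = np.log([c.shoal_size for c in cls])
        groups = [c.origin_config for c in cls]
        import pandas as pd

        ref = pairwise_tukeyhsd(y, groups)
        summary = pd.DataFrame(
            ref.summary().data[1:], columns=ref.summary().data[0]
        )
        ref_p = {
            tuple(sorted((r.group1, r.group2))): p
            for (_, r), p in zip(summary.iterrows(), ref.pvalues)
        }
        for _, row in fit.contrasts.iterrows():
            key = tuple(sorted((row.group_1, row.group_2)))
            assert row.p_tukey == pytest.approx(ref_p[key], abs=1e-6)

    def test_small_group_error_names_group(self):
        cls = make_classifications(
            [
                ("native_only", "mono_specific", 4),
                ("range_extending_only", "mono_specific", 5),
                ("range_extending_only", "mono_specific", 6),
            ]
        )
        with pytest.raises(FittingError, match="native_only"):
            sm.fit_shoal_size_model(cls)

    def test_full_model_aic_reported(self):
        rng = np.random.default_rng(13)
        cls = self.simulate(rng, [1.0, 1.5, 2.0])
        fit = sm.fit_shoal_size_model(cls)
        assert fit.aic_full is not None
        assert math.isfinite(fit.aic_reduced)
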