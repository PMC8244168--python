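"""Exclusion cascade and the three under-ascertainment corrections."""

import numpy as np
import pandas as pd
import pytest

from iccmap.corrections import (
    apply_exclusions,
    bma_pool,
    correction_one,
    correction_two,
    full_correction,
    linked_fraction,
    oversample_count,
    sentinel_inflation,
)
from iccmap.simulate import LinkageConfig, simulate_registry


def registry_from_strata(n_unlinked, n_geocode, n_early, n_region, n_clean):
    """Disjoint-strata registry: each case fails at most one rule."""
    rows = []

    def add(n, **flags):
        for _ in range(n):
            rows.append(
                dict(
                    area_id="a0",
                    age_group="g0",
                    year=2004,
                    linked=flags.get("linked", True),
                    private=False,
                    diagnosis_offset_days=flags.get("offset", 100.0)
                    if flags.get("linked", True)
                    else np.nan,
                    geocode_valid=flags.get("geocode", True),
                    excluded_region=flags.get("region", False),
                )
            )

    add(n_unlinked, linked=False)
    add(n_geocode, geocode=False)
    add(n_early, offset=-1000.0)
    add(n_region, region=True)
    add(n_clean)
    return pd.DataFrame(rows)


class TestExclusionCascade:
    def test_published_stratum_counts_reproduce_survivors(self):
        """57,161 cases; 32,393 unlinked, 1,607 bad geocodes, 3,666
        diagnosed 2+ years before the first HIV test, 1,674 in the
        excluded region -> 17,821 analytic cases."""
        reg = registry_from_strata(32393, 1607, 3666, 1674, 17821)
        assert len(reg) == 57161
        survivors, report = apply_exclusions(reg)
        assert len(survivors) == 17821
        assert [r[1] for r in report.steps] == [32393, 1607, 3666, 1674]
        assert report.final == 17821

    def test_clean_registry_removes_nothing(self):
        reg = registry_from_strata(0, 0, 0, 0, 25)
        survivors, report = apply_exclusions(reg)
        assert len(survivors) == 25
        assert all(r[1] == 0 for r in report.steps)

    def test_idempotent(self):
        reg = registry_from_strata(5, 3, 2, 1, 9)
        once, _ = apply_exclusions(reg)
        twice, rep = apply_exclusions(once)
        assert len(twice) == len(once)
        assert all(r[1] == 0 for r in rep.steps)

    def test_order_permutation_changes_counts_not_survivors(self, rng):
        """Overlapping strata: per-rule counts depend on order, the
        survivor set does not. Oracle: direct set logic on 20 cases."""
        df = pd.DataFrame(
            {
                "area_id": ["a0"] * 20,
                "age_group": ["g0"] * 20,
                "year": [2004] * 20,
                "linked": rng.random(20) < 0.7,
                "private": False,
                "geocode_valid": rng.random(20) < 0.8,
                "excluded_region": rng.random(20) < 0.2,
            }
        )
        df["diagnosis_offset_days"] = np.where(
            df["linked"], np.where(rng.random(20) < 0.3, -900.0, 50.0), np.nan
        )
        df["case_id"] = np.arange(20)
        oracle_keep = (
            df["linked"]
            & df["geocode_valid"]
            & ~df["excluded_region"]
            & ~(df["diagnosis_offset_days"] < -730)
        )
        order_a = ("unlinked", "geocode", "early_diagnosis", "excluded_region")
        order_b = ("excluded_region", "early_diagnosis", "geocode", "unlinked")
        surv_a, rep_a = apply_exclusions(df, order_a)
        surv_b, rep_b = apply_exclusions(df, order_b)
        assert set(surv_a["case_id"]) == set(surv_b["case_id"]) == set(
            df.loc[oracle_keep, "case_id"]
        )

    def test_two_year_boundary_is_inclusive(self):
        # exactly -730 days (two years to the day) stays eligible
        df = registry_from_strata(0, 0, 0, 0, 1)
        df.loc[0, "diagnosis_offset_days"] = -730.0
        surv, _ = apply_exclusions(df)
        assert len(surv) == 1

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusions(registry_from_strata(0, 0, 0, 0, 2), ("bogus",))


class TestCorrectionOneArithmetic:
    def make_registry(self, n_total=57161, n_unlinked=32564, n_unlinked_private=5077):
        linked = np.ones(n_total, bool)
        linked[:n_unlinked] = False
        private = np.zeros(n_total, bool)
        private[:n_unlinked_private] = True  # the unlinked private stratum
        return pd.DataFrame(
            {
                "area_id": "a0",
                "age_group": "g0",
                "year": 2004,
                "linked": linked,
                "private": private,
                "diagnosis_offset_days": np.where(linked, 10.0, np.nan),
                "geocode_valid": True,
                "excluded_region": False,
            }
        )

    def test_published_linked_fraction(self):
        reg = self.make_registry()
        assert round(linked_fraction(reg), 2) == 0.43

    def test_published_oversample_count(self):
        # floor(5,077 * 0.43...) with the exact fraction = 2,183
        reg = self.make_registry()
        assert oversample_count(reg) == 2183

    def test_zero_fraction_means_no_oversampling(self, small_panel):
        reg = self.make_registry(n_total=100, n_unlinked=100, n_unlinked_private=10)
        assert linked_fraction(reg) == 0.0
        assert oversample_count(reg) == 0


class TestCorrectionOneResampling:
    def test_replicates_add_cases_and_preserve_observed(self, small_panel, small_registry):
        res = correction_one(small_registry.icc, small_panel, m_replicates=4, seed=9)
        assert len(res) == 4
        n_over = res[0].n_oversampled
        for r in res:
            assert r.method == "I"
            added = r.additions.sum()
            assert 0 <= added <= n_over
            np.testing.assert_allclose(r.counts - r.additions, small_panel.y)
            assert np.all(r.additions == np.round(r.additions))

    def test_deterministic_under_seed(self, small_panel, small_registry):
        a = correction_one(small_registry.icc, small_panel, m_replicates=2, seed=3)
        b = correction_one(small_registry.icc, small_panel, m_replicates=2, seed=3)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)

    def test_errors_without_donor_pool(self, small_panel):
        reg = TestCorrectionOneArithmetic().make_registry()
        reg["private"] = ~reg["linked"]  # no linked private cases
        with pytest.raises(ValueError):
            correction_one(reg, small_panel, m_replicates=1, seed=0)


class TestCorrectionTwo:
    def make_sentinel(self, n=10000, p_linked=0.70, p_priv_unl=0.273, seed=0, area="a0"):
        rng = np.random.default_rng(seed)
        linked = rng.random(n) < p_linked
        private = np.where(linked, False, rng.random(n) < p_priv_unl)
        return pd.DataFrame({"area_id": area, "linked": linked, "private": private})

    def test_national_shares_reproduce_published_percentages(self):
        """70% linked, 8.2% of all sentinel cases unlinked-private ->
        21.8% unlinked non-private; q = 0.218/0.70."""
        n = 23046
        n_linked = round(0.70 * n)
        n_unl_priv = 1890
        linked = np.zeros(n, bool)
        linked[:n_linked] = True
        private = np.zeros(n, bool)
        private[n_linked : n_linked + n_unl_priv] = True
        sent = pd.DataFrame({"area_id": "a0", "linked": linked, "private": private})
        unl_np = (~linked) & (~private)
        assert (~linked).sum() / n == pytest.approx(0.30, abs=0.001)
        assert private.sum() / n == pytest.approx(0.082, abs=0.001)
        assert unl_np.sum() / n == pytest.approx(0.218, abs=0.001)
        _, q_nat = sentinel_inflation(sent, ("a0",))
        assert q_nat == pytest.approx(unl_np.sum() / n_linked)

    def test_zero_inflation_identity(self, small_panel):
        sent = self.make_sentinel(p_linked=1.0, area=small_panel.areas[0])
        with pytest.warns(UserWarning):
            res = correction_two(small_panel, sent)
        np.testing.assert_allclose(res.counts, small_panel.y)

    def test_multiplier_definition_single_area(self):
        from tests_helpers_panel import single_area_panel

        panel = single_area_panel(cases=10)
        sent = pd.DataFrame(
            {
                "area_id": [panel.areas[0]] * 3,
                "linked": [True, True, False],
                "private": [False, False, False],
            }
        )
        res = correction_two(panel, sent)
        assert res.counts.sum() == pytest.approx(15.0)  # q = 1/2

    def test_corrected_never_below_observed(self, small_panel, small_registry):
        res = correction_two(small_panel, small_registry.sentinel)
        assert np.all(res.counts >= small_panel.y - 1e-12)

    def test_large_registry_concentrates_on_national_inflation(self, small_panel):
        sent = self.make_sentinel(n=200000, seed=3, area=small_panel.areas[0])
        with pytest.warns(UserWarning):
            res = correction_two(small_panel, sent)
        linked = sent["linked"]
        q_expected = ((~linked) & (~sent["private"])).sum() / linked.sum()
        ratio = res.counts.sum() / small_panel.y.sum()
        assert ratio == pytest.approx(1 + q_expected, rel=1e-9)
        assert 1 + q_expected == pytest.approx(1 + 0.30 * (1 - 0.273) / 0.70, abs=0.01)


class TestFullCorrection:
    def test_additions_are_additive(self, small_panel, small_registry):
        c1 = correction_one(small_registry.icc, small_panel, m_replicates=3, seed=1)
        c2 = correction_two(small_panel, small_registry.sentinel)
        full = full_correction(c1, c2)
        assert len(full) == 3
        for f, a in zip(full, c1):
            np.testing.assert_allclose(
                f.counts - small_panel.y, a.additions + c2.additions
            )

    def test_empty_corrections_identity(self, small_panel):
        sent = pd.DataFrame(
            {"area_id": [small_panel.areas[0]] * 2, "linked": [True, True],
             "private": [False, False]}
        )
        reg = TestCorrectionOneArithmetic().make_registry(100, 100, 0)
        c1 = correction_one(reg, small_panel, m_replicates=2, seed=0)
        with pytest.warns(UserWarning):
            c2 = correction_two(small_panel, sent)
        full = full_correction(c1, c2)
        for f in full:
            np.testing.assert_allclose(f.counts, small_panel.y)

    def test_observed_le_corr2_le_full_in_expectation(self, small_panel, small_registry):
        c1 = correction_one(small_registry.icc, small_panel, m_replicates=5, seed=2)
        c2 = correction_two(small_panel, small_registry.sentinel)
        full = full_correction(c1, c2)
        mean_full = np.mean([f.counts for f in full], axis=0)
        assert small_panel.y.sum() <= c2.counts.sum() <= mean_full.sum()


class FakeDraws:
    """Minimal stand-in with the PosteriorDraws array layout, for
    pooling arithmetic tests (synthetic, not a fitted posterior)."""

    def __init__(self, values, seed=0):
        import iccmap.inference as inf
        from iccmap.model import ModelSpec

        s = len(values)
        vals = np.asarray(values, float)
        self._d = inf.PosteriorDraws(
            spec=ModelSpec(include_age=False, include_time=False,
                           include_space=False, include_interaction=False),
            areas=("a0",), age_groups=("g0",), years=(2004,),
            beta_names=[], alpha=vals, beta=np.zeros((s, 0)),
            u=np.zeros((s, 0)), v=np.zeros((s, 0)), b=np.zeros((s, 0)),
            gamma=np.zeros((s, 0)), delta=np.zeros((s, 0)),
            theta=np.zeros((s, 0, 0)), hyper={},
            eta=vals[:, None], loglik=np.zeros((s, 1)),
            eta_mean=np.array([vals.mean()]), log_offset=np.zeros(1), seed=seed,
        )


class TestBmaPool:
    def test_single_replicate_is_identity(self):
        d = FakeDraws([1.0, 2.0])._d
        assert bma_pool([d]) is d

    def test_two_point_masses_pool_to_order_statistics(self):
        a = FakeDraws([1.0] * 4)._d
        b = FakeDraws([3.0] * 4)._d
        pooled = bma_pool([a, b])
        assert pooled.n_draws == 8
        assert np.median(pooled.alpha) == pytest.approx(2.0)

    def test_pooled_variance_at_least_mean_within_variance(self, rng):
        reps = [FakeDraws(rng.normal(m, 0.5, 50))._d for m in (0.0, 1.0, 2.0)]
        pooled = bma_pool(reps)
        within = np.mean([r.alpha.var() for r in reps])
        assert pooled.alpha.var() >= within

    def test_unequal_draw_counts_subsampled_with_warning(self):
        a = FakeDraws([1.0] * 6)._d
        b = FakeDraws([2.0] * 4)._d
        with pytest.warns(UserWarning):
            pooled = bma_pool([a, b])
        assert pooled.n_draws == 8
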