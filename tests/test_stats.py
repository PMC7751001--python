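"""Tests for group comparison: KS statistic, summaries, dispersion."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lsomorph import (
    CohortConfig,
    InvalidInputError,
    MetricRecord,
    SpeciesRecord,
    generate_cohort,
    group_summary,
    intraspecific_spread,
    ks_by_flag,
    ks_statistic,
    ks_two_sample,
    morphospace_table,
)

from .oracles import naive_ks_d

samples = st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=30)


class TestKS:
    def test_identical_samples_give_zero(self, rng):
        x = rng.normal(size=15)
        assert ks_statistic(x, x) == 0.0

    def test_disjoint_supports_give_one(self):
        res = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.d_statistic == 1.0

    def test_interleaved_samples(self):
        assert ks_statistic([1, 3, 5, 7], [2, 4, 6, 8]) == pytest.approx(0.25)

    def test_matches_naive_enumeration_small_grid(self):
        """Exhaustive agreement with the double-loop oracle (n1,n2 <= 4 over 1..4)."""
        pools = [
            list(c)
            for n in range(1, 5)
            for c in itertools.combinations_with_replacement(range(1, 5), n)
        ]
        for x in pools:
            for y in pools:
                assert ks_statistic(x, y) == pytest.approx(naive_ks_d(x, y), abs=1e-12)

    @given(samples, samples)
    def test_symmetry(self, x, y):
        assert ks_statistic(x, y) == pytest.approx(ks_statistic(y, x), abs=1e-12)

    def test_shifting_a_sample_copy_never_decreases_d(self, rng):
        """D(x, x+delta) is nondecreasing in delta >= 0.

        (For two independent samples a shift can re-align them and lower D,
        so the monotone-separation law is tested on shifted copies, where it
        is a theorem: D is the largest fraction of x in a window of width
        delta, and windows nest.)
        """
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(3, 15)))
            deltas = np.sort(rng.uniform(0.0, 5.0, 6))
            ds = [ks_statistic(x, x + d) for d in deltas]
            assert all(b >= a - 1e-12 for a, b in zip(ds, ds[1:]))

    def test_large_shift_separates_independent_samples(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=8)
        span = x.max() - y.min() + 1.0
        assert ks_statistic(x, y + span) == 1.0

    def test_exact_method_for_small_tieless_samples(self, rng):
        res = ks_two_sample(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "exact"
        assert res.n_group1 == res.n_group2 == 20

    def test_ties_fall_back_to_asymptotic_with_warning(self):
        with pytest.warns(UserWarning, match="ties"):
            res = ks_two_sample([1, 2, 2, 3], [2, 4, 5])
        assert res.method == "asymptotic"

    def test_large_samples_use_asymptotic(self, rng):
        res = ks_two_sample(rng.normal(size=150), rng.normal(size=150))
        assert res.method == "asymptotic"

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            ks_two_sample([], [1.0])

    def test_p_value_matches_r_convention_on_known_sample(self, rng):
        # exact two-sided p for D=1 with n=3 vs 3 is 2*3!3!/6! = 0.1
        res = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-9)


def _cohort(n_specimens=1, seed=0, **kw):
    return generate_cohort(
        CohortConfig(n_specimens_per_species=n_specimens, seed=seed, **kw)
    )


class TestGroupSummary:
    def test_pooled_summary_matches_generator_parameters(self):
        species, metrics = _cohort(seed=4)
        pos, neg = group_summary(metrics, species, "lstc_prominence", "perching")
        pooled = np.array([m.lstc_prominence for m in metrics])
        assert pos.n + neg.n == 44
        # no group shift: both group means within 2 SE of the pooled mean
        se = pooled.std(ddof=1) / np.sqrt(pooled.size)
        for summ in (pos, neg):
            assert abs(summ.mean - pooled.mean()) < 2 * se * np.sqrt(2.0)

    def test_single_species_group_is_degenerate(self):
        species, metrics = _cohort(n_species=5, group_fraction=0.2, seed=1)
        pos, neg = group_summary(metrics, species, "lstc_prominence", "perching")
        assert pos.n == 1 and pos.degenerate and pos.sd == 0.0
        assert neg.n == 4 and not neg.degenerate

    def test_missing_species_metadata_is_keyed_error(self):
        species, metrics = _cohort(seed=0)
        with pytest.raises(InvalidInputError, match="Synthavis_sp001"):
            group_summary(metrics, species[1:], "lstc_prominence", "perching")

    def test_unknown_field_rejected(self):
        species, metrics = _cohort(seed=0)
        with pytest.raises(InvalidInputError):
            group_summary(metrics, species, "wingspan", "perching")


class TestMorphospace:
    def test_one_row_per_species_sorted(self):
        species, metrics = _cohort(seed=0)
        table = morphospace_table(metrics, species)
        assert len(table) == 44
        assert list(table["species_id"]) == sorted(table["species_id"])
        assert set(table.columns) >= {
            "lstc_prominence", "expansion_ratio",
            "terrestrial", "perching", "fly", "float", "dive",
        }

    def test_empty_metrics_give_empty_table(self):
        table = morphospace_table([], [])
        assert len(table) == 0

    def test_multi_specimen_species_collapse_to_means(self):
        species, metrics = _cohort(n_species=5, n_specimens=4, seed=9)
        table = morphospace_table(metrics, species)
        assert len(table) == 5
        for sid in table["species_id"]:
            mine = [m.lstc_prominence for m in metrics if m.species_id == sid]
            row = table.loc[table["species_id"] == sid, "lstc_prominence"].iloc[0]
            assert row == pytest.approx(np.mean(mine), rel=1e-12)

    def test_duplicate_species_rows_rejected(self):
        species, metrics = _cohort(seed=0)
        with pytest.raises(InvalidInputError, match="duplicate"):
            morphospace_table(metrics, species + [species[0]])


def _records(values_by_species):
    out = []
    for sid, vals in values_by_species.items():
        for j, (p, e) in enumerate(vals):
            out.append(
                MetricRecord(f"{sid}_{j}", sid, p, e, n_sections=0, ratios=None)
            )
    return out


class TestIntraspecificSpread:
    def test_identical_specimens_have_zero_within_variance(self):
        recs = _records({
            "Sp_a": [(0.1, 3.0)] * 3,
            "Sp_b": [(0.2, 4.0)] * 3,
        })
        table, ratios = intraspecific_spread(recs)
        np.testing.assert_allclose(table["prominence_sd"], 0.0, atol=1e-12)
        assert ratios["lstc_prominence"] == pytest.approx(0.0, abs=1e-12)

    def test_conforming_cohort_has_ratio_below_one(self):
        _, metrics = _cohort(n_species=10, n_specimens=5, seed=3)
        _, ratios = intraspecific_spread(metrics)
        assert ratios["lstc_prominence"] < 1.0
        assert ratios["expansion_ratio"] < 1.0

    def test_equal_within_and_between_dispersion_gives_ratio_near_one(self, rng):
        """Our ratio falls inside the central interval of a simulation oracle."""
        n_sp, n_spec, sd = 30, 6, 0.3
        oracle = []
        for _ in range(300):
            sp_means = rng.normal(0.0, sd, n_sp)
            vals = sp_means[:, None] + rng.normal(0.0, sd, (n_sp, n_spec))
            within = np.mean(np.var(vals, axis=1, ddof=1))
            between = np.var(vals.mean(axis=1), ddof=1)
            oracle.append(within / between)
        lo, hi = np.quantile(oracle, [0.005, 0.995])
        rng2 = np.random.default_rng(11)
        sp_means = rng2.normal(0.0, sd, n_sp)
        vals = np.exp(sp_means[:, None] + rng2.normal(0.0, sd, (n_sp, n_spec)))
        recs = _records({
            f"Sp_{i:02d}": [(v, v) for v in vals[i]] for i in range(n_sp)
        })
        _, ratios = intraspecific_spread(recs)
        # log-normal skew widens the band slightly; the oracle interval on the
        # normal scale still brackets the computed ratio
        assert lo * 0.5 < ratios["lstc_prominence"] < hi * 2.0

    def test_insufficient_replication_rejected(self):
        recs = _records({"Sp_a": [(0.1, 3.0)] * 3, "Sp_b": [(0.2, 4.0)]})
        with pytest.raises(InvalidInputError):
            intraspecific_spread(recs)


def test_ks_by_flag_uses_species_level_values():
    species, metrics = _cohort(n_species=12, n_specimens=3, seed=6)
    res = ks_by_flag(metrics, species, "lstc_prominence", "perching")
    assert res.n_group1 + res.n_group2 == 12
    assert 0.0 <= res.d_statistic <= 1.0
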