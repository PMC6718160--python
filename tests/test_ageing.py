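"""Reader-agreement statistics, MIR periodicity, ALK, otolith weight."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scarid.ageing import (
    age_length_key,
    ape_cv,
    disagreement_profiles,
    marginal_increment_ratio,
    mir_seasonality,
    otolith_weight_age_fit,
    readings_by_fish,
)
from scarid.io_core import OtolithRecord
from scarid.synthetic_data import SimConfig, simulate_population


def _oto(radii, radius, month=6, fish="f1", reading=1):
    return OtolithRecord(
        fish_id=fish,
        reading_id=reading,
        ring_radii=tuple(radii),
        otolith_radius=radius,
        capture_month=month,
    )


class TestApeCv:
    def test_identical_readings_give_zero(self):
        out = ape_cv({"a": [4, 4], "b": [7, 7]})
        assert out.ape == 0.0 and out.cv == 0.0

    def test_hand_computed_pair(self):
        out = ape_cv({"a": [4, 6]})
        assert out.ape == pytest.approx(20.0)
        assert out.cv == pytest.approx(100 * np.sqrt(2) / 5, abs=0.01)  # 28.28

    def test_single_reads_raise(self):
        with pytest.raises(ValueError):
            ape_cv({"a": [4], "b": [6]})

    @given(
        st.lists(
            st.tuples(st.integers(1, 25), st.integers(1, 25)),
            min_size=1,
            max_size=30,
        )
    )
    def test_cv_dominates_ape_for_two_readings(self, pairs):
        readings = {str(i): list(p) for i, p in enumerate(pairs)}
        out = ape_cv(readings)
        assert out.cv >= out.ape - 1e-9

    def test_reader_relabelling_is_irrelevant(self):
        a = ape_cv({"x": [4, 6], "y": [10, 9]})
        b = ape_cv({"x": [6, 4], "y": [9, 10]})
        assert a.ape == b.ape and a.cv == b.cv

    def test_simulated_ape_matches_analytic_expectation(self):
        """Two otolith readings with discrete truncated-Gaussian count errors:
        the observed APE must sit inside the Monte-Carlo band around the
        expectation enumerated over all error combinations."""
        base = SimConfig(n_fish=400, seed=17, reader_error_sd=0.0)
        noisy = SimConfig(n_fish=400, seed=17, reader_error_sd=0.5)
        _, oto_true = simulate_population(base)
        _, oto_noisy = simulate_population(noisy)
        truth = {o.fish_id: o.ring_count for o in oto_true if o.reading_id == 1}

        # per-fish error: round(N(0, sd * age / age_ref)) clipped to [-3, 3]
        from scipy.stats import norm

        ks = np.arange(-3, 4)

        def error_pmf(sd):
            pk = np.array(
                [norm.cdf(k + 0.5, scale=sd) - norm.cdf(k - 0.5, scale=sd) for k in ks]
            )
            pk[0] += norm.cdf(-3.5, scale=sd)
            pk[-1] += norm.sf(3.5, scale=sd)
            return pk

        per_fish_expected, per_fish_var = [], []
        for a in truth.values():
            pk = error_pmf(noisy.reader_error_sd * a / noisy.reader_age_ref)
            vals, probs = [], []
            for k1, p1 in zip(ks, pk):
                for k2, p2 in zip(ks, pk):
                    x1, x2 = max(a + k1, 1), max(a + k2, 1)
                    m = (x1 + x2) / 2
                    vals.append(abs(x1 - x2) / (2 * m) * 100 if m > 0 else 0.0)
                    probs.append(p1 * p2)
            vals, probs = np.array(vals), np.array(probs)
            mu = float(vals @ probs)
            per_fish_expected.append(mu)
            per_fish_var.append(float((vals - mu) ** 2 @ probs))
        expected = np.mean(per_fish_expected)
        mc_se = np.sqrt(np.sum(per_fish_var)) / len(per_fish_expected)

        observed = ape_cv(readings_by_fish(oto_noisy)).ape
        assert abs(observed - expected) < 4 * mc_se


class TestDisagreement:
    def test_all_equal_reads_give_zero_pd(self):
        out = disagreement_profiles({"a": [5, 5], "b": [8, 8]})
        assert (out["pd"] == 0).all()

    def test_enumerated_class(self):
        out = disagreement_profiles({"a": [5, 6], "b": [5, 5], "c": [5, 7]})
        row = out[out["age_class"] == 5].iloc[0]
        assert row["pd"] == pytest.approx(2 / 3)
        assert row["ird"] == pytest.approx(1.0)

    def test_pd_non_decreasing_with_noise(self):
        def mean_pd(sd, seed):
            cfg = SimConfig(n_fish=300, seed=seed, reader_error_sd=sd)
            _, oto = simulate_population(cfg)
            prof = disagreement_profiles(readings_by_fish(oto))
            return np.average(prof["pd"], weights=prof["n"])

        assert mean_pd(1.5, 4) > mean_pd(0.3, 4)


class TestMir:
    def test_full_increment_margin(self):
        assert marginal_increment_ratio(_oto([1.8, 2.2], 2.6)) == pytest.approx(1.0)

    def test_ring_at_edge(self):
        assert marginal_increment_ratio(_oto([1.8, 2.2], 2.2)) == pytest.approx(0.0)

    def test_half_increment(self):
        assert marginal_increment_ratio(_oto([1.0, 2.0], 2.5)) == pytest.approx(0.5)

    def test_fewer_than_two_rings_excluded(self):
        with pytest.raises(ValueError):
            marginal_increment_ratio(_oto([1.8], 2.6))

    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        base = marginal_increment_ratio(_oto([1.0, 2.0], 2.5))
        scaled = marginal_increment_ratio(
            _oto([1.0 * scale, 2.0 * scale], 2.5 * scale)
        )
        assert scaled == pytest.approx(base, rel=1e-9)


class TestMirSeasonality:
    def test_identical_months_give_null_t(self):
        otoliths = []
        for m in (5, 6):
            for i, mir_target in enumerate((0.4, 0.5, 0.6)):
                # radii chosen so MIR = mir_target with unit last increment
                otoliths.append(
                    _oto([1.0, 2.0], 2.0 + mir_target, month=m, fish=f"m{m}i{i}")
                )
        monthly, tests, _ = mir_seasonality(otoliths, reading_id=1)
        row = tests[(tests.month_a == 5) & (tests.month_b == 6)].iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-9)
        assert row["p"] == pytest.approx(1.0, abs=1e-9)

    def test_welch_t_on_printed_toy_samples(self):
        otoliths = []
        for i, v in enumerate((0.9, 1.0, 1.1)):
            otoliths.append(_oto([1.0, 2.0], 2.0 + v, month=1, fish=f"a{i}"))
        for i, v in enumerate((0.1, 0.2, 0.3)):
            otoliths.append(_oto([1.0, 2.0], 2.0 + v, month=2, fish=f"b{i}"))
        _, tests, _ = mir_seasonality(otoliths, reading_id=1, month_pairs=[(1, 2)])
        assert tests["t"].iloc[0] == pytest.approx(9.798, abs=0.01)

    def test_annulus_window_recovered_from_generator(self):
        cfg = SimConfig(n_fish=800, seed=23, reader_error_sd=0.0)
        fish, otoliths = simulate_population(cfg)
        tl = {r.fish_id: r.total_length for r in fish}
        _, _, annulus = mir_seasonality(
            otoliths, lengths_by_fish=tl, max_length=50.0
        )
        assert set(annulus) <= {11, 12}


class TestAgeLengthKey:
    def test_single_fish_single_cell(self):
        key = age_length_key([4], [47.0])
        assert key.loc[45.0, 4] == 1
        assert key.to_numpy().sum() == 1

    def test_totals_conserved(self, stratified_sample):
        _, fish, otoliths = stratified_sample
        from scarid.synthetic_data import ages_from_readings

        ages = ages_from_readings(otoliths, "2")
        tl = {r.fish_id: r.total_length for r in fish}
        pairs = [(ages[f], tl[f]) for f in ages]
        key = age_length_key([p[0] for p in pairs], [p[1] for p in pairs])
        assert key.to_numpy().sum() == len(pairs)

    def test_large_fish_are_old(self, stratified_sample):
        _, fish, otoliths = stratified_sample
        from scarid.synthetic_data import ages_from_readings

        ages = ages_from_readings(otoliths, "2")
        tl = {r.fish_id: r.total_length for r in fish}
        pairs = [(ages[f], tl[f]) for f in ages]
        key = age_length_key([p[0] for p in pairs], [p[1] for p in pairs])
        big = key.loc[key.index >= 70.0]
        modal_ages = big.columns[big.to_numpy().argmax(axis=1)]
        assert (modal_ages >= 8).all()


class TestOtolithWeightAge:
    def test_exact_line(self):
        out = otolith_weight_age_fit([0.2, 0.4, 0.6, 0.8], [1, 2, 3, 4])
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(0.2)

    def test_noiseless_generator_slope(self):
        cfg = SimConfig(n_fish=100, seed=2, reader_error_sd=0.0, oto_weight_sd=0.0)
        fish, otoliths = simulate_population(cfg)
        from scarid.synthetic_data import decimal_ages_from_readings

        ages = decimal_ages_from_readings(otoliths, "2")
        pairs = [
            (o.otolith_weight, ages[o.fish_id])
            for o in otoliths
            if o.reading_id == 2
        ]
        out = otolith_weight_age_fit([p[0] for p in pairs], [p[1] for p in pairs])
        assert out["slope"] == pytest.approx(cfg.oto_weight_slope, rel=1e-3)

    def test_permuted_ages_destroy_fit(self):
        r2 = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ages = rng.uniform(1, 20, 200)
            weights = 0.05 + 0.12 * ages + rng.normal(0, 0.05, 200)
            out = otolith_weight_age_fit(weights, rng.permutation(ages))
            r2.append(out["r_squared"])
        assert np.median(r2) < 0.05

    def test_degenerate_ages_raise(self):
        with pytest.raises(ValueError):
            otolith_weight_age_fit([0.1, 0.2, 0.3], [5, 5, 5])
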