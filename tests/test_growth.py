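"""VBGF fitting, Kimura comparison and ABI back-calculation."""

import numpy as np
import pytest

from scarid.growth import (
    back_calculate_abi,
    estimate_abi_exponent,
    fit_vbgf,
    kimura_lrt,
)
from scarid.io_core import AnalysisConfig, OtolithRecord
from scarid.synthetic_data import SimConfig, simulate_population, vbgf

TRUE = (85.28, 0.14, 0.16)


class TestVbgfFit:
    def test_noiseless_data_recovered_to_six_digits(self):
        ages = np.arange(1.0, 23.0)
        lengths = vbgf(ages, *TRUE)
        fit = fit_vbgf(ages, lengths)
        assert fit.linf == pytest.approx(TRUE[0], rel=1e-6)
        assert fit.k == pytest.approx(TRUE[1], rel=1e-6)
        assert fit.t0 == pytest.approx(TRUE[2], abs=1e-5)
        assert fit.rss < 1e-12

    def test_curve_is_zero_at_t0(self):
        ages = np.arange(1.0, 23.0)
        fit = fit_vbgf(ages, vbgf(ages, *TRUE))
        assert fit.predict(fit.t0) == pytest.approx(0.0, abs=1e-9)

    def test_unit_equivariance(self, rng):
        ages = np.arange(1.0, 16.0)
        lengths = vbgf(ages, *TRUE) + rng.normal(0, 2, ages.size)
        f1 = fit_vbgf(ages, lengths)
        f10 = fit_vbgf(ages, lengths * 10)
        assert f10.linf == pytest.approx(10 * f1.linf, rel=1e-5)
        assert f10.se_linf == pytest.approx(10 * f1.se_linf, rel=1e-4)
        assert f10.k == pytest.approx(f1.k, rel=1e-5)
        assert f10.t0 == pytest.approx(f1.t0, abs=1e-5)

    def test_needs_four_distinct_ages(self):
        with pytest.raises(ValueError, match="distinct ages"):
            fit_vbgf([1, 1, 2, 3], [10, 11, 18, 24])

    def test_rss_matches_brute_force_grid(self, rng):
        """Independent oracle: exhaustive grid search over (Linf, K, t0)
        on a 10-point dataset must not beat the optimizer by more than
        the grid resolution."""
        ages = np.linspace(1, 18, 10)
        lengths = vbgf(ages, *TRUE) + rng.normal(0, 3, 10)
        fit = fit_vbgf(ages, lengths)

        grid_linf = np.linspace(60, 110, 41)
        grid_k = np.linspace(0.05, 0.35, 41)
        grid_t0 = np.linspace(-2, 2, 41)
        best = np.inf
        for linf in grid_linf:
            pred = 1.0 - np.exp(
                -grid_k[:, None, None] * (ages[None, None, :] - grid_t0[None, :, None])
            )
            rss = ((linf * pred - lengths[None, None, :]) ** 2).sum(axis=-1)
            best = min(best, rss.min())
        assert fit.rss <= best + 1e-9

    def test_boundary_fit_is_flagged_not_adjusted(self, rng):
        # young-ages-only data cannot pin the asymptote
        ages = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0] * 4)
        lengths = 12.0 * ages ** 0.9 + rng.normal(0, 0.5, ages.size)
        fit = fit_vbgf(ages, lengths)
        if fit.linf > 2 * lengths.max():
            assert fit.boundary_warning


class TestKimura:
    def test_identical_groups_give_zero_statistics(self):
        ages = np.arange(1.0, 15.0)
        lengths = vbgf(ages, *TRUE)
        res = kimura_lrt((ages, lengths), (ages, lengths))
        for row in res:
            assert row.chisq == pytest.approx(0.0, abs=1e-6)
            assert row.p == pytest.approx(1.0, abs=1e-6)

    def test_statistic_is_nonnegative_on_random_data(self, rng):
        for _ in range(5):
            a1 = rng.uniform(1, 20, 40)
            a2 = rng.uniform(1, 20, 40)
            l1 = vbgf(a1, *TRUE) * (1 + rng.normal(0, 0.1, 40))
            l2 = vbgf(a2, 70.0, 0.2, -0.5) * (1 + rng.normal(0, 0.1, 40))
            for row in kimura_lrt((a1, l1), (a2, l2)):
                assert row.failed or row.chisq >= 0

    def test_df_layout(self):
        ages = np.arange(1.0, 15.0)
        res = kimura_lrt((ages, vbgf(ages, *TRUE)), (ages, vbgf(ages, *TRUE)))
        assert [r.df for r in res] == [1, 1, 1, 3]


class TestAbi:
    CFG = AnalysisConfig(
        biological_intercept_length=0.0, biological_intercept_radius=1e-9
    )

    def test_ring_at_capture_radius_returns_capture_length(self):
        oto = OtolithRecord("f", 1, (2.0, 4.0), 4.0)
        out = back_calculate_abi(oto, 80.0, self.CFG, exponent=1.0)
        assert out[-1] == pytest.approx(80.0)

    def test_linear_proportionality(self):
        oto = OtolithRecord("f", 1, (1.0, 2.0), 4.0)
        out = back_calculate_abi(oto, 80.0, self.CFG, exponent=1.0)
        assert out == pytest.approx([20.0, 40.0], rel=1e-6)

    def test_generator_round_trip_is_exact(self):
        cfg = SimConfig(n_fish=50, seed=6, reader_error_sd=0.0)
        fish, otoliths = simulate_population(cfg)
        tl = {r.fish_id: r.total_length for r in fish}
        ana = AnalysisConfig(
            biological_intercept_length=13.5,
            biological_intercept_radius=cfg.biological_intercept_radius(13.5),
        )
        checked = 0
        for o in otoliths:
            if o.reading_id != 2 or o.ring_count < 2:
                continue
            out = back_calculate_abi(
                o, tl[o.fish_id], ana, exponent=cfg.abi_exponent_true
            )
            # the generator draws every radius from the single allometry
            # TL = coef * R^c, so ABI must return exactly those lengths
            expected = cfg.oto_coef * np.asarray(o.ring_radii) ** cfg.abi_exponent_true
            # capture lengths are recorded to 0.01 cm, which propagates
            assert np.allclose(out, expected, atol=0.02, rtol=1e-4)
            assert out[-1] <= tl[o.fish_id] + 1e-9
            checked += 1
        assert checked > 20

    def test_last_ring_never_exceeds_capture_length(self):
        cfg = SimConfig(n_fish=40, seed=8, reader_error_sd=0.0)
        fish, otoliths = simulate_population(cfg)
        tl = {r.fish_id: r.total_length for r in fish}
        ana = AnalysisConfig(
            biological_intercept_length=13.5,
            biological_intercept_radius=cfg.biological_intercept_radius(13.5),
        )
        for o in otoliths:
            if o.reading_id != 2 or o.ring_count < 2:
                continue
            out = back_calculate_abi(o, tl[o.fish_id], ana, exponent=cfg.abi_exponent_true)
            assert out[-1] <= tl[o.fish_id] + 1e-9

    def test_intercept_radius_must_be_below_capture(self):
        cfg = AnalysisConfig(
            biological_intercept_length=13.5, biological_intercept_radius=5.0
        )
        oto = OtolithRecord("f", 1, (1.0, 2.0), 4.0)
        with pytest.raises(ValueError):
            back_calculate_abi(oto, 80.0, cfg, exponent=1.0)


class TestAbiExponent:
    def test_noiseless_power_law(self, rng):
        radii = rng.uniform(1, 10, 50)
        lengths = 7.0 * radii**1.2
        assert estimate_abi_exponent(lengths, radii)["c"] == pytest.approx(1.2)

    def test_isometric_data(self, rng):
        radii = rng.uniform(1, 10, 50)
        assert estimate_abi_exponent(radii * 8.0, radii)["c"] == pytest.approx(1.0)

    def test_recovery_under_noise_within_3_se(self, rng):
        radii = rng.uniform(1, 10, 200)
        lengths = 7.0 * radii**1.2 * np.exp(rng.normal(0, 0.05, 200))
        out = estimate_abi_exponent(lengths, radii)
        assert abs(out["c"] - 1.2) < 3 * out["se_c"]

    def test_nonpositive_values_raise(self):
        with pytest.raises(ValueError):
            estimate_abi_exponent([10.0] * 10, [0.0] + [1.0] * 9)
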