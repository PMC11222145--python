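import numpy as np
import pytest

from viralhist.growth import (GrowthCurve, compare_conditions, fit_gompertz,
                              fits_table, gompertz_model, read_growth_csv)
from viralhist.simulate import synth_growth

TIMES = np.arange(0.0, 24.0 + 1e-9, 0.5)


class TestModel:
    def test_asymptote(self):
        assert gompertz_model(1e6, 1.0, 0.2, 5.0) == pytest.approx(1.0)

    def test_value_at_lag_time(self):
        # exponent is exactly 1 at t = λ
        A = 0.8
        assert gompertz_model(5.0, A, 0.2, 5.0) == \
            pytest.approx(A * np.exp(-np.e), abs=1e-12)

    def test_inflection_value_and_slope(self):
        A, mu, lam = 0.9, 0.15, 6.0
        ti = lam + A / (mu * np.e)
        assert gompertz_model(ti, A, mu, lam) == pytest.approx(A / np.e)
        h = 1e-6
        slope = (gompertz_model(ti + h, A, mu, lam)
                 - gompertz_model(ti - h, A, mu, lam)) / (2 * h)
        assert slope == pytest.approx(mu, abs=1e-6)

    def test_max_slope_is_mu_on_dense_grid(self):
        A, mu, lam = 1.2, 0.3, 4.0
        t = np.linspace(0, 30, 200_001)
        y = gompertz_model(t, A, mu, lam)
        assert np.max(np.diff(y) / np.diff(t)) == pytest.approx(mu, rel=1e-2)

    def test_tangent_at_inflection_crosses_zero_at_lambda(self):
        A, mu, lam = 0.7, 0.25, 3.5
        ti = lam + A / (mu * np.e)
        y_i = gompertz_model(ti, A, mu, lam)
        assert ti - y_i / mu == pytest.approx(lam, abs=1e-6)

    def test_strictly_increasing_and_bounded(self):
        t = np.linspace(2, 40, 500)  # range where y is representable
        y = gompertz_model(t, 1.0, 0.2, 5.0)
        assert np.all(np.diff(y) > 0)
        assert np.all((y > 0) & (y < 1.0))

    def test_invalid_A(self):
        with pytest.raises(ValueError):
            gompertz_model(1.0, -1.0, 0.2, 5.0)


class TestFit:
    def test_noiseless_recovery(self):
        y = gompertz_model(TIMES, 1.0, 0.2, 5.0)
        f = fit_gompertz(GrowthCurve("s", "c", 1, TIMES, y))
        assert f.converged
        assert f.A == pytest.approx(1.0, rel=1e-4)
        assert f.mu == pytest.approx(0.2, rel=1e-4)
        assert f.lam == pytest.approx(5.0, rel=1e-4)

    def test_blank_is_subtracted(self):
        y = gompertz_model(TIMES, 1.0, 0.2, 5.0) + 0.05
        f = fit_gompertz(GrowthCurve("s", "c", 1, TIMES, y, blank=0.05))
        assert f.A == pytest.approx(1.0, rel=1e-4)

    def test_constant_blank_data_does_not_converge(self):
        y = np.full_like(TIMES, 0.05)
        f = fit_gompertz(GrowthCurve("s", "c", 1, TIMES, y, blank=0.05))
        assert not f.converged

    def test_decreasing_data_does_not_converge(self):
        y = np.linspace(1.0, 0.2, TIMES.size)
        f = fit_gompertz(GrowthCurve("s", "c", 1, TIMES, y))
        assert not f.converged

    def test_noisy_recovery_median_error_under_5pct(self):
        rng = np.random.default_rng(101)
        truth = (1.0, 0.2, 5.0)
        clean = gompertz_model(TIMES, *truth)
        errs = []
        for i in range(50):
            y = np.clip(clean + rng.normal(0, 0.01, TIMES.size), 0, None)
            f = fit_gompertz(GrowthCurve("s", "c", i, TIMES, y), seed=i)
            assert f.converged
            errs.append([abs(f.A - truth[0]) / truth[0],
                         abs(f.mu - truth[1]) / truth[1],
                         abs(f.lam - truth[2]) / truth[2]])
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.05)

    def test_amplitude_sanity_envelope(self):
        rng = np.random.default_rng(7)
        clean = gompertz_model(TIMES, 0.8, 0.25, 6.0)
        for i in range(10):
            y = np.clip(clean + rng.normal(0, 0.01, TIMES.size), 0, None)
            f = fit_gompertz(GrowthCurve("s", "c", i, TIMES, y), seed=i)
            top = float(np.max(y))
            assert f.converged and 0.5 * top <= f.A <= 2.0 * top


class TestCompare:
    @staticmethod
    def _make_fits(label, values):
        from viralhist.growth import GompertzFit
        return [GompertzFit(label, "std", i, A=v, mu=0.2, lam=5.0, rss=0.0,
                            converged=True, n_iter=10)
                for i, v in enumerate(values)]

    def test_single_group_single_letter(self):
        fits = {"a": self._make_fits("a", [1.0, 1.1, 0.9])}
        comp = compare_conditions(fits, "A")
        assert comp.letters == {"a": "a"}

    def test_distant_groups_get_distinct_letters(self):
        rng = np.random.default_rng(5)
        fits = {
            "low": self._make_fits("low", rng.normal(1.0, 0.05, 6)),
            "high": self._make_fits("high", rng.normal(3.0, 0.05, 6)),
        }
        comp = compare_conditions(fits, "A")
        assert comp.letters["low"] != comp.letters["high"]

    def test_identical_distribution_shares_letter(self):
        rng = np.random.default_rng(6)
        fits = {k: self._make_fits(k, rng.normal(1.0, 0.1, 6)) for k in "abc"}
        comp = compare_conditions(fits, "A")
        assert len({v for v in comp.letters.values()}) >= 1
        shared = set(comp.letters["a"]) & set(comp.letters["b"]) \
            & set(comp.letters["c"])
        assert shared  # no spurious separation at these effect sizes

    def test_null_familywise_error_near_alpha(self):
        rng = np.random.default_rng(77)
        alpha = 0.05
        reps, rejections = 500, 0
        for _ in range(reps):
            fits = {k: self._make_fits(k, rng.normal(0, 1, 5)) for k in "abcd"}
            comp = compare_conditions(fits, "A", alpha=alpha, bonferroni_m=1)
            groups = list(fits)
            if any(len(set(comp.letters[g]) & set(comp.letters[h])) == 0
                   for i, g in enumerate(groups) for h in groups[i + 1:]):
                rejections += 1
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_small_group_excluded_with_warning(self):
        fits = {
            "ok": self._make_fits("ok", [1.0, 1.1, 1.05]),
            "tiny": self._make_fits("tiny", [2.0]),
        }
        with pytest.warns(UserWarning, match="tiny"):
            comp = compare_conditions(fits, "A")
        assert set(comp.letters) == {"ok"}


class TestEndToEnd:
    def test_synthetic_lag_contrast_separates_letters(self, tmp_path):
        # two strains differing by 4 h of lag, 3 replicates, σ = 0.01
        groups = {"control": (1.0, 0.2, 5.0), "induced": (1.0, 0.2, 9.0)}
        df, _ = synth_growth(groups, n_replicates=3, noise_sd=0.01, seed=11,
                             out_dir=tmp_path)
        curves = read_growth_csv(tmp_path / "growth.csv")
        assert len(curves) == 6
        fits = {}
        for c in curves:
            fits.setdefault(c.strain, []).append(fit_gompertz(c))
        comp = compare_conditions(fits, "lam")
        assert set(comp.letters["control"]) & set(comp.letters["induced"]) \
            == set()
        table = fits_table([f for g in fits.values() for f in g])
        assert table["converged"].all()
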