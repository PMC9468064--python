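"""Growth-model evaluation, peak finding and inhibition classification."""

import math

import numpy as np
import pytest

import phakinetics as pk
from phakinetics.models import MODELS, ParameterSet


def grid_argmax(params: ParameterSet, upper: float, n: int = 100_000):
    """Brute-force oracle: dense-grid maximizer of μ on (0, upper]."""
    grid = np.linspace(upper / n, upper, n)
    mu = pk.evaluate(params, grid)
    i = int(np.argmax(mu))
    return float(grid[i]), float(mu[i])


class TestEvaluate:
    def test_monod_vanishes_at_zero_substrate(self):
        assert pk.evaluate(pk.CRUDE_SCG_ESTIMATES["monod"], 0.0) == 0.0

    def test_monod_half_saturation(self):
        # at C0 = Ks the Monod rate is exactly mu_max / 2
        mu = pk.evaluate(ParameterSet("monod", {"mu_max": 0.144, "Ks": 0.69}), 0.69)
        assert mu == pytest.approx(0.072, abs=1e-12)

    def test_han_levenspiel_zero_at_critical(self, hl_crude):
        assert pk.evaluate(hl_crude, 28.50) == 0.0

    def test_han_levenspiel_saponified_near_peak(self, hl_saponified):
        # reported peak rate on saponified oil at C0 = 9.94 g C/L
        assert pk.evaluate(hl_saponified, 9.94) == pytest.approx(0.1444, abs=5e-4)

    @pytest.mark.parametrize("model", ["han_levenspiel", "luong"])
    def test_zero_beyond_critical_concentration(self, model):
        params = pk.CRUDE_SCG_ESTIMATES[model]
        cmax = params["Cmax"]
        c = np.linspace(cmax, 3 * cmax, 50)
        assert np.all(pk.evaluate(params, c) == 0.0)

    def test_negative_c0_rejected(self, hl_crude):
        with pytest.raises(ValueError):
            pk.evaluate(hl_crude, -1.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(KeyError):
            ParameterSet("gompertz", {"mu_max": 0.1})

    def test_out_of_bounds_parameter_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet("monod", {"mu_max": -0.1, "Ks": 0.69})
        with pytest.raises(ValueError):
            ParameterSet("han_levenspiel",
                         {"mu_max": 0.1, "Ks": 1, "Cmax": 10, "n": -1, "m": 2})

    @pytest.mark.parametrize("substrate,presets", [
        ("crude", pk.CRUDE_SCG_ESTIMATES),
        ("saponified", pk.SAPONIFIED_SCG_ESTIMATES),
    ])
    def test_rate_never_exceeds_mu_max(self, substrate, presets):
        # Webb excluded: its (1 + C0/K) numerator can push mu above mu_max
        c = np.linspace(0, 40, 2001)
        for name, params in presets.items():
            if name == "webb":
                continue
            mu = pk.evaluate(params, c)
            assert np.all(mu <= params["mu_max"] + 1e-12), name


class TestModelNesting:
    def test_han_levenspiel_with_zero_exponents_is_monod(self):
        hl = ParameterSet("han_levenspiel",
                          {"mu_max": 0.144, "Ks": 0.69, "Cmax": 1e6, "n": 0.0, "m": 0.0})
        monod = ParameterSet("monod", {"mu_max": 0.144, "Ks": 0.69})
        c = np.linspace(1e-6, 100, 5000)
        np.testing.assert_allclose(pk.evaluate(hl, c), pk.evaluate(monod, c), rtol=1e-12)

    def test_luong_n1_is_monod_times_linear_cutoff(self):
        luong = ParameterSet("luong", {"mu_max": 0.15, "Ks": 1.0, "Cmax": 20.0, "n": 1.0})
        monod = ParameterSet("monod", {"mu_max": 0.15, "Ks": 1.0})
        c = np.linspace(1e-6, 19.999, 3000)
        expected = pk.evaluate(monod, c) * (1 - c / 20.0)
        np.testing.assert_allclose(pk.evaluate(luong, c), expected, rtol=1e-12)

    def test_han_levenspiel_n1_m0_is_monodlike_cutoff(self):
        hl = ParameterSet("han_levenspiel",
                          {"mu_max": 0.15, "Ks": 1.0, "Cmax": 20.0, "n": 1.0, "m": 0.0})
        c = np.linspace(1e-6, 19.999, 3000)
        expected = 0.15 * c * (1 - c / 20.0) / (c + 1.0)
        np.testing.assert_allclose(pk.evaluate(hl, c), expected, rtol=1e-12)


class TestShape:
    @pytest.mark.parametrize("name", ["monod", "moser"])
    def test_saturating_models_nondecreasing(self, name):
        params = pk.CRUDE_SCG_ESTIMATES[name]
        c = np.linspace(1e-6, 100, 4000)
        assert np.all(np.diff(pk.evaluate(params, c)) >= -1e-15)

    @pytest.mark.parametrize("name", ["aiba", "andrews", "haldane", "webb", "yano"])
    @pytest.mark.parametrize("presets", [pk.CRUDE_SCG_ESTIMATES, pk.SAPONIFIED_SCG_ESTIMATES])
    def test_inhibited_models_unimodal(self, name, presets):
        # discrete differences change sign at most once (rise then fall)
        params = presets[name]
        c = np.linspace(1e-4, 1000, 20000)
        d = np.sign(np.diff(pk.evaluate(params, c)))
        d = d[d != 0]
        changes = int(np.sum(d[1:] != d[:-1]))
        assert changes <= 1


class TestFindPeak:
    def test_crude_peak_matches_reported_values(self, hl_crude):
        c_peak, mu_peak = pk.find_peak(hl_crude)
        assert mu_peak == pytest.approx(0.139, rel=0.01)
        assert c_peak == pytest.approx(9.2, rel=0.01)

    def test_monod_peak_at_search_boundary(self):
        params = pk.CRUDE_SCG_ESTIMATES["monod"]
        c_peak, mu_peak = pk.find_peak(params, search_upper=10.0)
        assert c_peak == pytest.approx(10.0, abs=1e-3)
        assert mu_peak == pytest.approx(pk.evaluate(params, 10.0), rel=1e-6)

    def test_haldane_closed_form_argmax(self):
        # standard Haldane peaks at sqrt(Ks*Ki); with Ks=Ki=1: c*=1, mu*=1/3
        params = ParameterSet("haldane", {"mu_max": 1.0, "Ks": 1.0, "Ki": 1.0})
        c_peak, mu_peak = pk.find_peak(params, search_upper=50.0)
        assert c_peak == pytest.approx(1.0, abs=1e-4)
        assert mu_peak == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_requires_upper_bound_without_cmax(self):
        with pytest.raises(ValueError):
            pk.find_peak(pk.CRUDE_SCG_ESTIMATES["monod"])

    def test_agrees_with_dense_grid_oracle_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(3):
            for name in pk.MODEL_NAMES:
                params = random_valid_params(name, rng)
                upper = params.values.get("Cmax", 30.0)
                c_ref, mu_ref = grid_argmax(params, upper)
                c_hat, mu_hat = pk.find_peak(params, search_upper=upper)
                assert mu_hat >= mu_ref - 1e-9, name
                if name not in ("monod", "moser"):
                    assert abs(c_hat - c_ref) <= upper / 100_000 * 2, name


def random_valid_params(name: str, rng: np.random.Generator) -> ParameterSet:
    """Draw plausible positive parameters for one model."""
    spec = MODELS[name]
    vals = {}
    for sym in spec.parameter_symbols:
        if sym == "mu_max":
            vals[sym] = rng.uniform(0.05, 0.5)
        elif sym == "Ks":
            vals[sym] = rng.uniform(0.2, 5.0)
        elif sym in ("Ki", "K"):
            vals[sym] = rng.uniform(1.0, 100.0)
        elif sym == "Cmax":
            vals[sym] = rng.uniform(10.0, 40.0)
        else:  # n, m
            vals[sym] = rng.uniform(0.05, 4.0)
    return ParameterSet(name, vals)


class TestCriticalConcentration:
    def test_values(self, hl_saponified):
        assert pk.critical_concentration(hl_saponified) == pytest.approx(19.11)
        assert pk.critical_concentration(pk.CRUDE_SCG_ESTIMATES["luong"]) == pytest.approx(23.25)
        assert pk.critical_concentration(pk.CRUDE_SCG_ESTIMATES["monod"]) is None


class TestClassifyInhibition:
    @pytest.mark.parametrize("n,m,label", [
        (0.096, 8.995, "uncompetitive"),
        (0.058, 5.456, "uncompetitive"),
        (0.0, 0.0, "other"),
        (2.0, 1.0, "other"),
        (0.0, 3.0, "other"),  # m > n but n = 0
    ])
    def test_rule(self, n, m, label):
        assert pk.classify_inhibition(n, m).label == label

    def test_missing_exponents_not_applicable(self):
        assert pk.classify_inhibition(None, None).label == "not_applicable"

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            pk.classify_inhibition(-0.1, 1.0)


class TestParameterSetSerialization:
    def test_json_round_trip(self, hl_crude):
        restored = ParameterSet.from_json(hl_crude.to_json())
        assert restored == hl_crude

    def test_missing_model_key_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet.from_json('{"mu_max": 0.1}')
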