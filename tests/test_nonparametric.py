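import numpy as np
import pytest

from raresphere.data_model import AbundanceVector, FrequencyCounts
from raresphere.errors import ACEUndefinedError
from raresphere.nonparametric import (
    CollectorCurve,
    ace,
    chao1,
    collector_curve,
    fit_saturating_curves,
    ichao1,
    rarefy_richness,
)


def random_fc(rng, max_k=30, max_f=20):
    ks = rng.choice(np.arange(1, max_k + 1), size=rng.integers(2, 10), replace=False)
    return FrequencyCounts({int(k): int(rng.integers(1, max_f)) for k in ks})


class TestChao1:
    def test_no_singletons_degenerates_to_observed(self):
        fc = FrequencyCounts({2: 4, 7: 3})
        assert chao1(fc) == fc.s_obs

    def test_classical_arithmetic(self):
        fc = FrequencyCounts({1: 2, 2: 1, 5: 2})  # S_obs=5, F1=2, F2=1
        assert chao1(fc, bias_corrected=False) == 5 + 4 / 2

    def test_bias_corrected_arithmetic(self):
        fc = FrequencyCounts({1: 2, 5: 1})  # S_obs=3, F1=2, F2=0
        assert chao1(fc) == 3 + 2 * 1 / (2 * 1)

    def test_classical_falls_back_when_f2_zero(self):
        fc = FrequencyCounts({1: 2, 5: 1})
        assert chao1(fc, bias_corrected=False) == chao1(fc)


class TestIChao1:
    def test_no_f3_equals_chao1(self):
        fc = FrequencyCounts({1: 5, 2: 2, 9: 1})
        assert ichao1(fc) == chao1(fc)

    def test_published_formula_by_hand(self):
        fc = FrequencyCounts({1: 4, 2: 2, 3: 2, 4: 1})  # S_obs = 9
        # independent spreadsheet-style evaluation of the iChao1 formula
        s_chao = 9 + 4 * 3 / (2 * (2 + 1))
        corr = (2 / (4 * 1)) * max(4 - 2 * 2 / (2 * 1), 0)
        assert ichao1(fc) == pytest.approx(s_chao + corr)

    def test_never_below_chao1(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            fc = random_fc(rng)
            assert ichao1(fc) >= chao1(fc) - 1e-12


class TestACE:
    def test_no_rare_species_reduces_to_observed(self):
        fc = FrequencyCounts({12: 4, 20: 2})
        assert ace(fc) == 6.0

    def test_standard_formula_by_hand(self):
        fc = FrequencyCounts({1: 3, 2: 2, 12: 1})
        # independent arithmetic: S_rare=5, S_abund=1, N_rare=7, C=4/7,
        # sum k(k-1)F_k = 4, gamma^2 = max(5/(4/7)*4/42 - 1, 0) = 0
        assert ace(fc) == pytest.approx(1 + 5 / (4 / 7))

    def test_ace1_at_least_ace(self):
        rng = np.random.default_rng(1)
        n = 0
        while n < 100:
            fc = random_fc(rng, max_k=15)
            try:
                a, a1 = ace(fc), ace(fc, variant="ace1")
            except ACEUndefinedError:
                continue
            assert a1 >= a - 1e-12
            n += 1

    def test_all_singletons_coverage_zero(self):
        with pytest.raises(ACEUndefinedError):
            ace(FrequencyCounts({1: 10}))

    def test_label_free(self):
        # estimators depend on the frequency table only, not on ids
        av1 = AbundanceVector(("a", "b", "c"), np.array([1, 1, 4]))
        av2 = AbundanceVector(("x", "y", "z"), np.array([4, 1, 1]))
        from raresphere.data_model import to_frequency_counts

        assert chao1(to_frequency_counts(av1)) == chao1(to_frequency_counts(av2))


class TestRarefaction:
    def test_full_depth_returns_observed(self, tiny_av):
        assert rarefy_richness(tiny_av, tiny_av.n_reads) == tiny_av.s_obs

    def test_single_read_single_species(self):
        av = AbundanceVector(("a", "b"), np.array([2, 1]))
        assert rarefy_richness(av, 1) == pytest.approx(1.0)

    def test_matches_monte_carlo(self, tiny_av):
        e, v = rarefy_richness(tiny_av, 4, variance=True)
        rng = np.random.default_rng(0)
        reads = np.repeat(np.arange(4), tiny_av.counts)
        sims = np.array(
            [
                len(np.unique(rng.choice(reads, 4, replace=False)))
                for _ in range(100_000)
            ]
        )
        se = sims.std(ddof=1) / np.sqrt(len(sims))
        assert abs(e - sims.mean()) < 3 * se
        assert v == pytest.approx(sims.var(ddof=1), rel=0.05)

    def test_oversampling_rejected(self, tiny_av):
        with pytest.raises(ValueError):
            rarefy_richness(tiny_av, tiny_av.n_reads + 1)


@pytest.fixture(scope="module")
def community():
    rng = np.random.default_rng(5)
    counts = np.concatenate(
        [rng.integers(20, 200, size=30), rng.integers(1, 6, size=70)]
    )
    return AbundanceVector(
        tuple(f"o{i}" for i in range(100)), counts.astype(np.int64)
    )


class TestCollectorCurve:

    def test_single_point_grid_is_observed(self, community):
        N = community.n_reads
        cc = collector_curve(community, grid=[N], n_boot=20)
        assert cc.kind == ("observed",)
        assert cc.expected_richness[0] == community.s_obs

    def test_monotone_with_band(self, community):
        cc = collector_curve(
            community,
            extrapolate_to=4 * community.n_reads,
            n_boot=60,
            rng=np.random.default_rng(2),
        )
        assert np.all(np.diff(cc.expected_richness) >= -1e-9)
        assert np.all(cc.ci_low <= cc.expected_richness + 1e-9)
        assert np.all(cc.expected_richness <= cc.ci_high + 1e-9)
        kinds = np.array(cc.kind)
        assert set(kinds) == {"interpolated", "observed", "extrapolated"}

    def test_extrapolation_approaches_truth_from_below(self):
        # community simulated so chao1 is close to the true richness:
        # a sizeable rare-but-not-degenerate tail
        from raresphere.abundance_models import TADModel, sample_community, sample_counts
        from raresphere.data_model import to_frequency_counts

        rng = np.random.default_rng(12)
        S_true = 300
        m = TADModel("poisson_lognormal", (np.log(40.0), 1.0))
        p = sample_community(m, S_true, rng)
        c = sample_counts(p, 9000, rng)
        obs = c[c > 0]
        av = AbundanceVector(
            tuple(f"s{i}" for i in range(len(obs))), obs.astype(np.int64)
        )
        fc = to_frequency_counts(av)
        cc = collector_curve(
            av, extrapolate_to=10 * av.n_reads, n_boot=30, rng=rng
        )
        end = cc.expected_richness[-1]
        assert av.s_obs <= end <= max(chao1(fc), S_true) + 1
        if abs(chao1(fc) - S_true) / S_true < 0.1:
            assert end <= S_true * 1.1

    def test_no_singletons_extrapolates_flat(self):
        av = AbundanceVector(("a", "b", "c"), np.array([4, 5, 6]))
        cc = collector_curve(av, extrapolate_to=10 * av.n_reads, n_boot=10)
        assert cc.expected_richness[-1] == av.s_obs


class TestSaturatingFits:
    def flat_curve(self, value, n=10):
        x = np.linspace(1000, 10000, n)
        y = np.full(n, float(value))
        return CollectorCurve(x, y, y, y, ("interpolated",) * n, 10000, value)

    def test_exact_michaelis_menten_recovered(self):
        x = np.linspace(500, 50_000, 20)
        y = 1000 * x / (5000 + x)
        cv = CollectorCurve(x, y, y, y, ("interpolated",) * 20, 50_000, 500)
        res = fit_saturating_curves(cv)
        assert res[0].family == "michaelis_menten"
        assert res[0].asymptote == pytest.approx(1000.0, abs=1e-5)

    def test_flat_curve_asymptote_is_observed(self):
        res = fit_saturating_curves(self.flat_curve(250))
        assert res[0].asymptote == pytest.approx(250.0, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_saturating_curves(self.flat_curve(100, n=5))

    def test_asymptotes_bound_observed_richness(self, community=None):
        # realistic rising curve: every saturating family's asymptote
        # should not undershoot the curve's plateau region badly
        x = np.linspace(1000, 60_000, 15)
        y = 800 * (1 - np.exp(-x / 15_000))
        cv = CollectorCurve(x, y, y, y, ("interpolated",) * 15, 60_000, int(y[-1]))
        res = fit_saturating_curves(cv)
        assert res[0].asymptote >= y[-1]
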