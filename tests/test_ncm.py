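import numpy as np
import pandas as pd
import pytest

from phyloassembly import (
    fit_ncm,
    ncm_per_group,
    fit_lognormal_sad,
    fit_geometric_sad,
    octave_binning,
    simulate_metacommunity,
    simulate_neutral_table,
    simulate_selection_table,
    simulate_tree,
)
from phyloassembly.ncm import (
    fit_lognormal_octaves,
    fit_migration_rate,
    ncm_predicted_frequency,
)
from phyloassembly.rng import substream
from tests.conftest import make_table


class TestNcmFit:
    @pytest.mark.parametrize("detection", ["exact", "threshold"])
    def test_self_consistent_input_recovers_m_exactly(self, detection):
        p = np.geomspace(1e-5, 0.05, 200)
        freq = ncm_predicted_frequency(p, 0.3, 1000.0, detection)
        m, r2 = fit_migration_rate(p, freq, 1000.0, detection=detection)
        assert m == pytest.approx(0.3, rel=1e-5)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_dirichlet_multinomial_parameter_recovery(self):
        # Nm = 500 at N = 1000 reads -> m = 0.5
        errs = []
        for seed in range(3):
            mc = simulate_metacommunity(800, 2.0, seed=seed)
            tab = simulate_neutral_table(mc, Nm=500, n_samples=60, reads=1000, seed=seed)
            fit = fit_ncm(tab)
            errs.append(abs(fit.m - 0.5) / 0.5)
            assert fit.r2 > 0.2  # neutral data fits the neutral model well
        assert max(errs) < 0.25

    def test_selection_data_fits_worse_than_neutral(self):
        tree = simulate_tree(800, seed=1)
        mc = simulate_metacommunity(800, 2.0, seed=1)
        neutral = simulate_neutral_table(mc, Nm=500, n_samples=30, reads=1000, seed=1)
        env = substream(1, "env").normal(0, 1.5, size=30)
        selected = simulate_selection_table(tree, mc, env, sigma_w=0.15, reads=1000, seed=1)
        r2_neutral = fit_ncm(neutral).r2
        r2_selected = fit_ncm(selected).r2
        assert r2_selected < r2_neutral
        assert r2_neutral > 0.2

    def test_partition_exhaustive_and_exclusive(self):
        mc = simulate_metacommunity(300, 2.0, seed=2)
        tab = simulate_neutral_table(mc, 200, 20, 500, seed=2)
        fit = fit_ncm(tab)
        assert fit.partition_counts.sum() == len(fit.per_otu)
        assert fit.per_otu["predicted"].between(0, 1).all()
        assert fit.r2 <= 1.0

    def test_prediction_monotone_in_abundance(self):
        p = np.linspace(1e-5, 0.2, 100)
        f = ncm_predicted_frequency(p, 0.4, 1000.0)
        assert (np.diff(f) >= -1e-12).all()

    def test_band_widens_with_fewer_samples(self):
        from statsmodels.stats.proportion import proportion_confint

        pred = 0.6
        lo20, hi20 = proportion_confint(pred * 20, 20, method="wilson")
        lo60, hi60 = proportion_confint(pred * 60, 60, method="wilson")
        assert (hi20 - lo20) > (hi60 - lo60)

    def test_recovery_improves_with_sample_count(self):
        errs = {}
        for n in (20, 60):
            e = []
            for seed in range(10):
                mc = simulate_metacommunity(600, 2.0, seed=seed)
                tab = simulate_neutral_table(mc, 500, n, 1000, seed=seed + 10 * n)
                e.append(abs(fit_ncm(tab).m - 0.5))
            errs[n] = np.sqrt(np.mean(np.square(e)))
        assert errs[60] <= errs[20]

    def test_few_samples_warns(self):
        mc = simulate_metacommunity(50, 1.0, seed=3)
        tab = simulate_neutral_table(mc, 100, 5, 200, seed=3)
        with pytest.warns(UserWarning, match="samples"):
            fit_ncm(tab)

    def test_single_otu_rejected(self):
        with pytest.raises(ValueError):
            fit_ncm(make_table([[5, 3]]))


class TestNcmPerGroup:
    def test_single_group_matches_whole_table(self):
        mc = simulate_metacommunity(200, 1.5, seed=4)
        tab = simulate_neutral_table(mc, 300, 12, 500, seed=4)
        grouping = {s: "all" for s in tab.sample_ids}
        fits = ncm_per_group(tab, grouping)
        assert fits["all"].m == pytest.approx(fit_ncm(tab).m)

    def test_migration_rate_ordering_recovered(self):
        wins = 0
        for seed in range(3):
            mc = simulate_metacommunity(400, 2.0, seed=seed)
            hi = simulate_neutral_table(mc, 1000, 15, 1000, seed=seed)
            lo = simulate_neutral_table(mc, 100, 15, 1000, seed=seed + 50)
            hi.data.columns = [f"h{j}" for j in range(15)]
            lo.data.columns = [f"l{j}" for j in range(15)]
            merged = make_table(
                np.hstack([hi.data.to_numpy(), lo.data.to_numpy()]),
                taxa=mc.taxon_ids,
                samples=list(hi.data.columns) + list(lo.data.columns),
            )
            grouping = {s: ("hi" if s.startswith("h") else "lo") for s in merged.sample_ids}
            fits = ncm_per_group(merged, grouping)
            wins += fits["hi"].m > fits["lo"].m
        assert wins == 3

    def test_undersized_group_skipped_with_warning(self):
        mc = simulate_metacommunity(100, 1.0, seed=5)
        tab = simulate_neutral_table(mc, 200, 12, 300, seed=5)
        grouping = {s: ("tiny" if i < 2 else "big") for i, s in enumerate(tab.sample_ids)}
        with pytest.warns(UserWarning, match="tiny"):
            fits = ncm_per_group(tab, grouping)
        assert set(fits) == {"big"}


class TestOctaveBinning:
    def test_boundary_split_and_conservation(self):
        # abundances 1,2,3,4: powers of two split half/half
        octaves = octave_binning([1, 2, 3, 4])
        assert octaves.sum() == pytest.approx(4.0)
        assert octaves[0] == pytest.approx(0.5)  # half of the singleton
        assert octaves[2] == pytest.approx(2.0)  # 3 plus halves of 2 and 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            octave_binning([0, 0])


class TestSadFits:
    def test_noiseless_inversion(self):
        R = np.arange(13)
        y = 20 * np.exp(-(0.3**2) * (R - 6.0) ** 2)
        fit = fit_lognormal_octaves(pd.Series(y, index=pd.RangeIndex(13, name="octave")))
        assert abs(fit.S0 - 20) < 1e-6
        assert abs(fit.a - 0.3) < 1e-6
        assert fit.aic < -50  # near-zero residuals

    def test_fitted_curve_symmetric(self):
        mc = simulate_metacommunity(400, 2.0, seed=6)
        pooled = substream(6, "pool").multinomial(200_000, mc.p)
        fit = fit_lognormal_sad(pooled)
        R = np.array([0.5, 1.0, 2.5])
        np.testing.assert_allclose(fit.curve(R), fit.curve(-R))

    def test_lognormal_beats_geometric_on_lognormal_pool(self):
        wins = 0
        for seed in range(3):
            mc = simulate_metacommunity(500, 2.0, seed=seed)
            pooled = substream(seed, "pool").multinomial(500_000, mc.p)
            wins += fit_lognormal_sad(pooled).aic < fit_geometric_sad(pooled).aic
        assert wins == 3

    def test_single_octave_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal_sad([3, 3, 3, 3])
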