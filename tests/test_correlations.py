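from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from phyloassembly import env_distance, geo_distance, mantel, partial_mantel
from phyloassembly.matrices import PairwiseMatrix


def random_distance(n, seed, dims=5, name="d"):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dims))
    return PairwiseMatrix.from_values(
        squareform(pdist(X)), [f"s{i}" for i in range(n)], name
    )


class TestEnvDistance:
    def meta(self, values):
        return pd.DataFrame({"v": values}, index=[f"s{i}" for i in range(len(values))])

    def test_duplicate_samples_zero(self):
        d = env_distance(self.meta([3.0, 3.0, 5.0]), ["v"])
        assert d.values[0, 1] == 0.0

    def test_zscore_hand_value(self):
        # values 0,1,2 -> z = (-1, 0, 1) with sample sd; d(s0, s2) = 2
        d = env_distance(self.meta([0.0, 1.0, 2.0]), ["v"])
        assert d.values[0, 2] == pytest.approx(2.0)

    def test_affine_invariance(self):
        a = env_distance(self.meta([1.0, 4.0, 2.0, 9.0]), ["v"])
        b = env_distance(self.meta([10 + 3 * x for x in [1.0, 4.0, 2.0, 9.0]]), ["v"])
        np.testing.assert_allclose(a.values, b.values)

    def test_zero_variance_dropped(self):
        meta = pd.DataFrame(
            {"v": [1.0, 2.0, 3.0], "const": [7.0, 7.0, 7.0]},
            index=["s0", "s1", "s2"],
        )
        with pytest.warns(UserWarning, match="const"):
            d = env_distance(meta, ["v", "const"])
        assert d.values[0, 2] == pytest.approx(2.0)


class TestGeoDistance:
    def meta(self, coords):
        lat, lon = zip(*coords)
        return pd.DataFrame(
            {"latitude": lat, "longitude": lon},
            index=[f"s{i}" for i in range(len(coords))],
        )

    def test_same_point_zero(self):
        d = geo_distance(self.meta([(26.2, 98.5), (26.2, 98.5)]))
        assert d.values[0, 1] == 0.0

    def test_one_degree_latitude(self):
        d = geo_distance(self.meta([(0.0, 0.0), (1.0, 0.0)]))
        assert d.values[0, 1] == pytest.approx(111.19, abs=0.01)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(0)
        coords = list(zip(rng.uniform(-60, 60, 10), rng.uniform(-170, 170, 10)))
        v = geo_distance(self.meta(coords)).values
        np.testing.assert_allclose(v, v.T)
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geo_distance(self.meta([(95.0, 0.0), (0.0, 0.0)]))


class TestMantel:
    def test_self_correlation_is_one(self):
        d = random_distance(10, 1)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_exhaustive_enumeration_oracle_n4(self):
        dx = random_distance(4, 2, name="x")
        dy = random_distance(4, 3, name="y")
        x = dx.values[np.triu_indices(4, 1)]

        def corr(v):
            return np.corrcoef(x, v[np.triu_indices(4, 1)])[0, 1]

        r_obs = corr(dy.values)
        perm_rs = [corr(dy.values[np.ix_(p, p)]) for p in permutations(range(4))]
        p_exact = np.mean([r >= r_obs - 1e-12 for r in perm_rs])
        res = mantel(dx, dy, n_perm=10_000, seed=4)
        assert res.r == pytest.approx(r_obs)
        assert abs(res.p - p_exact) < 0.02

    def test_matches_skbio_oracle(self):
        dx = random_distance(12, 5, name="x")
        dy_vals = 0.5 * dx.values + 0.5 * random_distance(12, 6).values
        dy = PairwiseMatrix.from_values(dy_vals, dx.sample_ids, "y")
        ours = mantel(dx, dy, n_perm=999, seed=7)
        r_ref, p_ref, _ = skbio_mantel(
            DistanceMatrix(dx.values, dx.sample_ids),
            DistanceMatrix(dy.values, dy.sample_ids),
            permutations=999,
            alternative="greater",
            seed=7,
        )
        assert ours.r == pytest.approx(r_ref, abs=1e-12)
        assert abs(ours.p - p_ref) < 0.05

    def test_spearman_monotone_invariance(self):
        dx = random_distance(10, 8, name="x")
        dy = random_distance(10, 9, name="y")
        dy_mono = PairwiseMatrix.from_values(dy.values**3, dy.sample_ids, "y3")
        a = mantel(dx, dy, method="spearman", n_perm=99, seed=1)
        b = mantel(dx, dy_mono, method="spearman", n_perm=99, seed=1)
        assert a.r == pytest.approx(b.r)
        assert a.p == pytest.approx(b.p)

    def test_p_never_zero_and_bounded(self):
        dx = random_distance(8, 10)
        dy = PairwiseMatrix.from_values(dx.values * 2, dx.sample_ids, "y")
        res = mantel(dx, dy, n_perm=199, seed=2)
        assert res.p >= 1 / 200
        assert -1 <= res.r <= 1

    def test_mismatched_ids_rejected(self):
        dx = random_distance(6, 11)
        dy = PairwiseMatrix.from_values(
            random_distance(6, 12).values, [f"q{i}" for i in range(6)], "y"
        )
        with pytest.raises(ValueError):
            mantel(dx, dy, n_perm=9, seed=0)


class TestPartialMantel:
    def test_fully_controlled_partial_r_near_zero(self):
        dy = random_distance(20, 13, name="y")
        dx = PairwiseMatrix.from_values(
            dy.values + random_distance(20, 14).values, dy.sample_ids, "x"
        )
        res = partial_mantel(dx, dy, dy, n_perm=99, seed=3)
        assert abs(res.r) < 1e-9

    def test_uncorrelated_control_matches_plain_mantel(self):
        n = 50
        shared = random_distance(n, 15).values
        dx = PairwiseMatrix.from_values(
            shared + 0.3 * random_distance(n, 16).values, [f"s{i}" for i in range(n)], "x"
        )
        dy = PairwiseMatrix.from_values(
            shared + 0.3 * random_distance(n, 17).values, [f"s{i}" for i in range(n)], "y"
        )
        dz = random_distance(n, 18, name="z")
        plain = mantel(dx, dy, n_perm=99, seed=5)
        partial = partial_mantel(dx, dy, dz, n_perm=99, seed=5)
        assert abs(plain.r - partial.r) < 0.05

    def test_r_bounded(self):
        dx, dy, dz = (random_distance(9, s, name=n) for s, n in [(20, "x"), (21, "y"), (22, "z")])
        res = partial_mantel(dx, dy, dz, n_perm=99, seed=6)
        assert -1 <= res.r <= 1
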