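"""Bray-Curtis distances, continuous-covariate PERMANOVA, and convergence tests."""

import itertools
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix

from otukit.beta_diversity import (
    bin_distance_test,
    bray_curtis,
    distances_to_reference,
    permanova_continuous,
)
from otukit.core_io import AnalysisConfig, CountTable

from .conftest import make_metadata, random_table


def brute_force_bray(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return np.abs(x - y).sum() / (x + y).sum()


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = CountTable(("o1", "o2"), ("a", "b"), np.array([[3, 3], [7, 7]]))
        assert bray_curtis(t)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        t = CountTable(("o1", "o2"), ("a", "b"), np.array([[5, 0], [0, 9]]))
        assert bray_curtis(t)["a", "b"] == 1.0

    def test_printed_example(self):
        t = CountTable(("o1", "o2", "o3"), ("x", "y"), np.array([[2, 1], [0, 1], [1, 0]]))
        assert bray_curtis(t)["x", "y"] == pytest.approx(0.6, abs=1e-15)

    def test_zero_total_sample_named(self):
        t = CountTable(("o1",), ("a", "empty"), np.array([[3, 0]]))
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(t)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_and_axioms(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_otus=10, n_samples=6, max_count=50)
        t = CountTable(t.otu_ids, t.sample_ids, t.counts + 1)  # positive totals
        dm = bray_curtis(t)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)
        assert dm.data.min() >= 0 and dm.data.max() <= 1
        for a, b in itertools.combinations(t.sample_ids, 2):
            assert dm[a, b] == pytest.approx(
                brute_force_bray(t.column(a), t.column(b)), abs=1e-12
            )


def _gower_oracle(dm_vals, cov):
    """Independent trace computation with explicit loops."""
    n = len(cov)
    a = -0.5 * dm_vals**2
    row = a.mean(axis=1)
    grand = a.mean()
    g = a - row[:, None] - row[None, :] + grand
    x = np.column_stack([np.ones(n), cov])
    h = x @ np.linalg.inv(x.T @ x) @ x.T
    ss_model = np.trace(h @ g @ h)
    ss_total = np.trace(g)
    ss_res = ss_total - ss_model
    f = (ss_model / 1) / (ss_res / (n - 2))
    return f, ss_model / ss_total, ss_model, ss_res, ss_total


class TestPermanova:
    def _random_dm(self, rng, n):
        t = random_table(rng, 12, n, max_count=80)
        t = CountTable(t.otu_ids, t.sample_ids, t.counts + 1)
        return bray_curtis(t)

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_pseudo_f_matches_trace_oracle(self, n):
        rng = np.random.default_rng(n)
        dm = self._random_dm(rng, n)
        cov = rng.normal(size=n)
        res = permanova_continuous(dm, cov, n_perm=9, seed=0)
        f, r2, ssm, ssr, sst = _gower_oracle(dm.data, cov)
        assert res.pseudo_f == pytest.approx(f, rel=1e-10)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)

    def test_ss_partition_additive(self):
        rng = np.random.default_rng(9)
        dm = self._random_dm(rng, 12)
        cov = rng.normal(size=12)
        f, r2, ssm, ssr, sst = _gower_oracle(dm.data, cov)
        # residual computed through the independent projector route
        n = 12
        a = -0.5 * dm.data**2
        j = np.eye(n) - np.ones((n, n)) / n
        g = j @ a @ j
        x = np.column_stack([np.ones(n), cov])
        h = x @ np.linalg.inv(x.T @ x) @ x.T
        resid = (np.eye(n) - h) @ g @ (np.eye(n) - h)
        assert ssm + np.trace(resid) == pytest.approx(sst, abs=1e-9)

    def test_exhaustive_enumeration_at_n5(self):
        rng = np.random.default_rng(2)
        dm = self._random_dm(rng, 5)
        cov = rng.normal(size=5)
        res = permanova_continuous(dm, cov, n_perm=999, seed=0)
        assert res.exhaustive and res.n_permutations == 120
        fs = []
        for p in itertools.permutations(range(5)):
            fs.append(_gower_oracle(dm.data, cov[list(p)])[0])
        expected = np.mean(np.array(fs) >= res.pseudo_f - 1e-12)
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_r2_invariant_under_affine_covariate(self):
        rng = np.random.default_rng(4)
        dm = self._random_dm(rng, 10)
        cov = rng.normal(size=10)
        a = permanova_continuous(dm, cov, n_perm=99, seed=0)
        b = permanova_continuous(dm, 3.5 * cov - 11.0, n_perm=99, seed=0)
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-10)
        assert a.pseudo_f == pytest.approx(b.pseudo_f, rel=1e-10)

    def test_constructed_gradient_recovered(self):
        z = np.arange(10, dtype=float)
        vals = np.abs(z[:, None] - z[None, :]) / z.max()
        dm = DistanceMatrix(vals, ids=[f"s{i}" for i in range(10)])
        res = permanova_continuous(dm, z, n_perm=999, seed=0)
        assert res.r_squared > 0.9
        assert res.p_value <= 1 / (res.n_permutations + (0 if res.exhaustive else 1)) + 1e-9

    def test_constant_covariate_rejected(self):
        rng = np.random.default_rng(5)
        dm = self._random_dm(rng, 6)
        with pytest.raises(ValueError, match="constant"):
            permanova_continuous(dm, np.ones(6), n_perm=9, seed=0)

    def test_agrees_with_vegan_adonis2(self):
        """Independent oracle: R vegan's adonis2 on the same distances."""
        rng = np.random.default_rng(3)
        n = 12
        counts = rng.integers(0, 100, (15, n))
        tab = CountTable(
            tuple(f"o{i}" for i in range(15)), tuple(f"s{j}" for j in range(n)), counts
        )
        dm = bray_curtis(tab)
        cov = rng.normal(size=n)
        res = permanova_continuous(dm, cov, n_perm=9, seed=0)
        script = (
            "suppressMessages(library(vegan));"
            f"x <- matrix(c({','.join(map(str, counts.T.flatten()))}), nrow={n}, byrow=TRUE);"
            f"age <- c({','.join(map(str, cov))});"
            'r <- adonis2(vegdist(x, method="bray") ~ age, permutations=9);'
            'cat(r$F[1], r$R2[1])'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        f_r, r2_r = map(float, out.stdout.split())
        assert res.pseudo_f == pytest.approx(f_r, rel=1e-5)
        assert res.r_squared == pytest.approx(r2_r, rel=1e-5)


class TestDistancesToReference:
    def _setup(self, rng, bins):
        rows = []
        for b, n in bins.items():
            for k in range(len(rows), len(rows) + n):
                rows.append({"sample_id": f"s{k}", "age_bin": b})
        meta = make_metadata(rows)
        n = len(rows)
        vals = rng.uniform(0.1, 0.9, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix(vals, ids=[r["sample_id"] for r in rows])
        return dm, meta

    def test_counts_and_brute_force(self, rng):
        dm, meta = self._setup(rng, {"ref": 4, "one": 1, "binB": 3})
        results = distances_to_reference(dm, meta, "ref")
        by_bin = {r.age_bin: r for r in results}
        assert by_bin["one"].distances.size == 4
        ref_ids = [s for s in dm.ids if meta.frame.loc[s, "age_bin"] == "ref"]
        for r in results:
            ids = [s for s in dm.ids if meta.frame.loc[s, "age_bin"] == r.age_bin]
            manual = sorted(dm[a, b] for a in ids for b in ref_ids)
            assert sorted(r.distances) == pytest.approx(manual)
        manual_within = sorted(
            dm[a, b] for a, b in itertools.combinations(ref_ids, 2)
        )
        assert sorted(by_bin["binB"].reference_within) == pytest.approx(manual_within)

    def test_identical_reference_within_zero(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.0
        vals[0, 2] = vals[2, 0] = 0.5
        vals[1, 2] = vals[2, 1] = 0.5
        dm = DistanceMatrix(vals, ids=["r1", "r2", "x"])
        meta = make_metadata(
            [
                {"sample_id": "r1", "age_bin": "ref"},
                {"sample_id": "r2", "age_bin": "ref"},
                {"sample_id": "x", "age_bin": "other"},
            ]
        )
        (res,) = distances_to_reference(dm, meta, "ref")
        assert (res.reference_within == 0).all()


class TestBinDistanceTest:
    def test_identical_multisets_p_one(self, rng):
        from otukit.beta_diversity import BinDistanceResult

        vals = rng.uniform(0.2, 0.8, size=10)
        r = BinDistanceResult("b", vals.copy(), vals.copy())
        (out,) = bin_distance_test([r])
        assert out.raw_p == 1.0

    def test_bonferroni_over_bins(self, rng):
        from otukit.beta_diversity import BinDistanceResult

        results = []
        for k in range(8):
            results.append(
                BinDistanceResult(
                    f"b{k}",
                    rng.uniform(0.5, 0.9, size=12),
                    rng.uniform(0.1, 0.5, size=12),
                )
            )
        out = bin_distance_test(results)
        for r in out:
            assert r.adjusted_p == pytest.approx(min(1.0, r.raw_p * 8), abs=1e-12)
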