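"""MAD filter, soft threshold, TOM, module detection, trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetcirc.modules import (
    ModuleError,
    compute_tom,
    detect_modules,
    eigengene_matrix,
    fallback_power,
    mad_filter,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    signed_adjacency,
)


def _expr(arr, prefix="f"):
    arr = np.atleast_2d(arr)
    return pd.DataFrame(arr,
                        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{i}" for i in range(arr.shape[1])])


def tom_brute_force(A):
    n = A.shape[0]
    T = np.eye(n)
    k = A.sum(axis=1) - np.diag(A)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n)
                       if u not in (i, j))
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestMADFilter:
    def test_constant_circ_removed_and_gene_quartile(self, rng):
        circ = _expr(np.vstack([np.ones(10),
                                rng.normal(size=(5, 10))]), "c")
        gene = _expr(rng.normal(size=(100, 10)), "g")
        out = mad_filter(circ, gene)
        assert "c0" not in out.index
        assert sum(1 for f in out.index if f.startswith("g")) == 25

    def test_matches_brute_force_ranking(self, rng):
        gene = _expr(rng.normal(size=(40, 12)), "g")
        out = mad_filter(_expr(rng.normal(size=(3, 12)), "c"), gene)
        kept = {f for f in out.index if f.startswith("g")}
        mads = {f: stats.median_abs_deviation(gene.loc[f])
                for f in gene.index}
        expect = set(sorted(mads, key=mads.get, reverse=True)[:10])
        assert kept == expect


class TestSoftThreshold:
    def _unfittable(self, n_samples, rng):
        """Near-constant mutual correlation: connectivity has no spread."""
        lat = rng.normal(size=n_samples)
        return _expr(lat[None, :] + 1e-3 * rng.normal(
            size=(60, n_samples)))

    @pytest.mark.parametrize("n,expect", [(16, 18), (25, 16), (35, 14),
                                          (45, 12)])
    def test_fallback_by_sample_size(self, n, expect, rng):
        power, _ = pick_soft_threshold(self._unfittable(n, rng))
        assert power == expect
        assert fallback_power(n) == expect

    def test_modular_data_matches_independent_scan(self, rng):
        lat = rng.normal(size=(4, 20))
        X = np.vstack([lat[i][None, :] + 0.7 * rng.normal(size=(25, 20))
                       for i in range(4)])
        expr = _expr(X)
        power, scan = pick_soft_threshold(expr)
        # independent re-scan of the published selection rule
        ok = scan[(scan["r2"] >= 0.85) & (scan["slope"] < 0)]
        expect = int(ok["power"].min()) if len(ok) else fallback_power(20)
        assert power == expect

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ModuleError):
            pick_soft_threshold(_expr(np.ones((2, 10))))


class TestTOM:
    def test_identity_adjacency(self):
        np.testing.assert_allclose(compute_tom(np.eye(6)), np.eye(6))

    def test_identical_neighborhoods_full_overlap(self):
        # connected nodes sharing a binary neighborhood overlap fully
        A = np.array([
            [1.0, 1.0, 1.0, 0.0],
            [1.0, 1.0, 1.0, 0.0],
            [1.0, 1.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ])
        assert compute_tom(A)[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            A = rng.random((20, 20))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            np.testing.assert_allclose(compute_tom(A), tom_brute_force(A),
                                       atol=1e-12)

    def test_bounds_symmetry_diagonal(self, rng):
        A = rng.random((15, 15))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = compute_tom(A)
        assert ((T >= 0) & (T <= 1)).all()
        np.testing.assert_allclose(T, T.T)
        np.testing.assert_allclose(np.diag(T), 1.0)

    def test_asymmetric_rejected(self, rng):
        A = rng.random((5, 5))
        with pytest.raises(ModuleError, match="symmetric"):
            compute_tom(A)


class TestEigengene:
    def test_identical_profiles(self, rng):
        profile = rng.normal(size=12)
        expr = _expr(np.tile(profile, (8, 1)) * rng.uniform(1, 5, (8, 1)))
        eig, varexp = module_eigengene(expr, expr.index)
        assert varexp == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert abs(np.corrcoef(eig, z)[0, 1]) == pytest.approx(1.0)
        # sign aligned with the mean standardized profile
        assert np.corrcoef(eig, z)[0, 1] > 0

    def test_matches_covariance_eigendecomposition(self, rng):
        expr = _expr(rng.normal(size=(20, 10)))
        eig, _ = module_eigengene(expr, expr.index)
        X = expr.to_numpy()
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        w, v = np.linalg.eigh(Z.T @ Z)
        top = v[:, -1]
        assert abs(np.dot(eig, top)) == pytest.approx(1.0, abs=1e-8)

    def test_member_permutation_invariance(self, rng):
        expr = _expr(rng.normal(size=(15, 10)))
        e1, _ = module_eigengene(expr, list(expr.index))
        perm = list(rng.permutation(expr.index))
        e2, _ = module_eigengene(expr, perm)
        np.testing.assert_allclose(np.abs(e1 @ e2), 1.0, atol=1e-8)

    def test_constant_module_rejected(self):
        with pytest.raises(ModuleError):
            module_eigengene(_expr(np.ones((4, 6))), [f"f{i}"
                                                      for i in range(4)])


def _planted(rng, sizes, noise=0.5, n_s=32, extra_noise=0):
    lat = rng.normal(size=(len(sizes), n_s))
    blocks = [lat[i][None, :] + noise * rng.normal(size=(k, n_s))
              for i, k in enumerate(sizes)]
    if extra_noise:
        blocks.append(rng.normal(size=(extra_noise, n_s)))
    X = np.vstack(blocks)
    labels = np.concatenate(
        [np.full(k, i) for i, k in enumerate(sizes)]
        + ([np.full(extra_noise, len(sizes))] if extra_noise else []))
    return _expr(X), labels


class TestDetectModules:
    def test_two_blocks_recovered_small_block_unassigned(self, rng):
        from sklearn.metrics import adjusted_rand_score
        expr, truth = _planted(rng, [60, 60, 30])
        asn = detect_modules(compute_tom(signed_adjacency(expr, 12)), expr)
        lab = asn["module"].to_numpy()
        big = truth < 2
        assert adjusted_rand_score(truth[big], lab[big]) >= 0.95
        assert (lab[truth == 2] == "grey").all()
        assert asn.loc[big, "kme"].min() > 0.5

    def test_same_latent_blocks_merge(self, rng):
        lat = rng.normal(size=32)
        X = np.vstack([lat + 0.5 * rng.normal(size=(60, 32)),
                       lat + 0.5 * rng.normal(size=(60, 32))])
        expr = _expr(X)
        asn = detect_modules(compute_tom(signed_adjacency(expr, 12)), expr)
        mods = set(asn["module"]) - {"grey"}
        assert len(mods) == 1

    def test_label_invariance_under_reordering(self, rng):
        expr, _ = _planted(rng, [55, 55])
        tom = compute_tom(signed_adjacency(expr, 12))
        a1 = detect_modules(tom, expr).set_index("feature_id")
        order = rng.permutation(len(expr))
        expr2 = expr.iloc[order]
        tom2 = compute_tom(signed_adjacency(expr2, 12))
        a2 = detect_modules(tom2, expr2).set_index("feature_id")
        assert (a1.loc[expr.index, "module"]
                == a2.loc[expr.index, "module"]).all()


class TestTraitCorrelation:
    def _eig(self, arr):
        return pd.DataFrame({"turquoise": arr},
                            index=[f"s{i}" for i in range(len(arr))])

    def test_zero_correlation_p_one(self, rng):
        x = np.concatenate([np.arange(10.0), np.arange(10.0)])
        y = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        out = module_trait_correlation(
            self._eig(x), pd.DataFrame({"RFI": y}, index=self._eig(x).index))
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_perfect_correlation(self, rng):
        x = rng.normal(size=20)
        out = module_trait_correlation(
            self._eig(x), pd.DataFrame({"RFI": 2 * x + 1},
                                       index=self._eig(x).index))
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-12
        assert out["significant"].iloc[0]

    def test_p_matches_student_transform(self, rng):
        x, y = rng.normal(size=(2, 24))
        out = module_trait_correlation(
            self._eig(x), pd.DataFrame({"RFI": y}, index=self._eig(x).index))
        r = out["r"].iloc[0]
        t = r * np.sqrt(22) / np.sqrt(1 - r * r)
        from scipy import stats as ss
        assert out["p"].iloc[0] == pytest.approx(2 * ss.t.sf(abs(t), 22))

    def test_constant_trait_reported_missing(self, rng):
        x = rng.normal(size=12)
        out = module_trait_correlation(
            self._eig(x), pd.DataFrame({"RFI": np.ones(12)},
                                       index=self._eig(x).index))
        assert np.isnan(out["r"].iloc[0])
        assert not out["significant"].iloc[0]

    def test_eigengene_matrix_excludes_grey(self, rng):
        expr = _expr(rng.normal(size=(10, 8)))
        asn = pd.DataFrame({
            "feature_id": expr.index,
            "module": ["turquoise"] * 5 + ["grey"] * 5,
            "kme": 1.0,
        })
        eig = eigengene_matrix(expr, asn)
        assert list(eig.columns) == ["turquoise"]
        assert len(eig) == 8
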