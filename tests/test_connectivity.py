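"""Orthogonalized AEC, connectome assembly, thresholding, strength."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from opmpipe import connectivity
from opmpipe.exceptions import EmptySetError, UndefinedStatisticError
from opmpipe.preprocess import bandpass_array
from opmpipe.synth import bandlimited_noise

FS = 375.0


def _beta_noise(n, seed):
    return bandlimited_noise(n, FS, 13, 30, np.random.default_rng(seed))


class TestOrthogonalize:
    def test_pure_leakage_removed(self):
        x = _beta_noise(5000, 0)
        assert np.abs(connectivity.orthogonalize_pair(x, 3 * x)).max() < 1e-12

    @given(seed=st.integers(0, 50))
    def test_residual_orthogonal_to_regressor(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 2000))
        y_perp = connectivity.orthogonalize_pair(x, y)
        assert abs(x @ y_perp) < 1e-8 * np.linalg.norm(x) * np.linalg.norm(y)

    def test_independent_signals_barely_changed(self):
        x = _beta_noise(100_000, 1)
        y = _beta_noise(100_000, 2)
        y_perp = connectivity.orthogonalize_pair(x, y)
        assert np.corrcoef(y, y_perp)[0, 1] > 0.99

    def test_zero_regressor_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            connectivity.orthogonalize_pair(np.zeros(100), np.ones(100))


class TestAEC:
    def test_identical_signals_give_zero(self):
        x = _beta_noise(50_000, 3)
        assert connectivity.aec(x, x.copy()) == 0.0

    def test_leakage_pair_stays_low(self):
        x = _beta_noise(112_500, 4)
        eps = 0.1 * _beta_noise(112_500, 5)
        assert abs(connectivity.aec(x, 0.8 * x + eps)) < 0.1

    def test_independent_signals_near_zero(self):
        n = int(300 * FS)
        vals = [connectivity.aec(_beta_noise(n, 10 + i), _beta_noise(n, 50 + i))
                for i in range(4)]
        assert np.abs(vals).max() < 0.05

    def test_monotone_in_planted_rho(self, truth):
        """Estimated AEC strictly increases over rho in {0.2, 0.4, 0.6},
        averaged across seeded cohorts."""
        from dataclasses import replace
        from opmpipe.synth import simulate_regional_sources
        means = []
        for rho in (0.2, 0.4, 0.6):
            vals = []
            for seed in (5, 11, 23):
                t0 = replace(truth, envelope_pairs=[(0, 1, rho)])
                S = bandpass_array(simulate_regional_sources(t0, 200.0, seed=seed),
                                   FS, 13, 30)
                vals.append(connectivity.aec(S[0], S[1]))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_downsampling_changes_little_for_smooth_envelopes(self):
        t = np.arange(int(60 * FS)) / FS
        env = 1 + 0.5 * np.sin(2 * np.pi * 0.3 * t)
        x = env * _beta_noise(t.size, 6)
        y = env * _beta_noise(t.size, 7)
        a75 = connectivity.aec(x, y, downsampled_rate=75.0)
        a375 = connectivity.aec(x, y, downsampled_rate=375.0)
        assert abs(a75 - a375) <= 0.02

    def test_constant_envelope_rejected(self):
        # a constant signal has a constant envelope: correlation undefined
        with pytest.raises(UndefinedStatisticError):
            connectivity.aec(np.ones(50_000), _beta_noise(50_000, 11))
        # pure multiples short-circuit to zero instead (leakage convention)
        assert connectivity.aec(np.ones(50_000), np.ones(50_000) * 2) == 0.0


class TestConnectome:
    def test_82_regions_evaluate_3321_pairs(self):
        rng = np.random.default_rng(8)
        S = bandpass_array(rng.standard_normal((82, int(40 * FS))), FS, 13, 30)
        cm = connectivity.build_connectome(S)
        assert cm.n_pairs == 3321
        off = ~np.eye(82, dtype=bool)
        assert np.isfinite(cm.matrix[off]).all()
        assert np.allclose(cm.matrix, cm.matrix.T)
        assert np.all(np.diag(cm.matrix) == 0)

    def test_two_regions_one_pair(self):
        S = bandpass_array(np.random.default_rng(9).standard_normal((2, 20_000)),
                           FS, 13, 30)
        cm = connectivity.build_connectome(S)
        assert cm.n_pairs == 1
        with pytest.raises(EmptySetError):
            connectivity.build_connectome(S[:1])

    def test_region_permutation_conjugates_matrix(self):
        rng = np.random.default_rng(10)
        S = bandpass_array(rng.standard_normal((5, 30_000)), FS, 13, 30)
        names = list("abcde")
        cm = connectivity.build_connectome(S, names)
        perm = [3, 1, 4, 0, 2]
        cm_p = connectivity.build_connectome(S[perm], [names[i] for i in perm])
        assert np.allclose(cm_p.matrix, cm.matrix[np.ix_(perm, perm)], atol=1e-12)


class TestThreshold:
    def _connectome(self, n=82, seed=0):
        rng = np.random.default_rng(seed)
        M = rng.uniform(-0.2, 0.8, (n, n))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        return connectivity.Connectome(matrix=M, region_names=[f"r{i}" for i in range(n)])

    def test_default_keeps_266_edges(self):
        edges = connectivity.threshold_edges(self._connectome())
        assert len(edges) == 266
        assert edges["weight"].is_monotonic_decreasing

    def test_k1_is_global_maximum(self):
        cm = self._connectome(n=10, seed=1)
        e = connectivity.threshold_edges(cm, k=1)
        iu, ju = np.triu_indices(10, 1)
        assert e["weight"].iloc[0] == cm.matrix[iu, ju].max()

    def test_injected_top_k_recovered(self):
        cm = self._connectome(n=20, seed=2)
        planted = [(0, 5), (3, 9), (12, 17)]
        for i, j in planted:
            cm.matrix[i, j] = cm.matrix[j, i] = 2.0 + i * 0.1
        e = connectivity.threshold_edges(cm, k=3)
        got = {(cm.region_names.index(a), cm.region_names.index(b))
               for a, b in zip(e["region_a"], e["region_b"])}
        assert got == set(planted)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            connectivity.threshold_edges(self._connectome(n=5), k=11)


class TestStrength:
    def test_uniform_matrix_closed_form(self):
        n, c = 7, 0.3
        M = np.full((n, n), c)
        np.fill_diagonal(M, 0.0)
        cm = connectivity.Connectome(matrix=M, region_names=[f"r{i}" for i in range(n)])
        s = connectivity.connectivity_strength(cm)
        assert np.allclose(s.to_numpy(), (n - 1) * c)
        # total strength = 2 x sum of the upper triangle
        iu, ju = np.triu_indices(n, 1)
        assert s.sum() == pytest.approx(2 * M[iu, ju].sum())

    def test_zero_matrix_zero_strength(self):
        cm = connectivity.Connectome(matrix=np.zeros((4, 4)),
                                     region_names=list("abcd"))
        assert connectivity.connectivity_strength(cm).sum() == 0.0

    def test_hub_region_has_max_strength(self):
        n = 10
        M = np.full((n, n), 0.05)
        M[2, :] = M[:, 2] = 0.5
        np.fill_diagonal(M, 0.0)
        cm = connectivity.Connectome(matrix=M, region_names=[f"r{i}" for i in range(n)])
        s = connectivity.connectivity_strength(cm)
        assert s.idxmax() == "r2"

    def test_subset_sum_and_unknown_region(self):
        cm = connectivity.Connectome(matrix=np.ones((3, 3)) - np.eye(3),
                                     region_names=list("abc"))
        s, tot = connectivity.connectivity_strength(cm, subset=["a", "b"])
        assert tot == 4.0
        with pytest.raises(KeyError):
            connectivity.connectivity_strength(cm, subset=["zzz"])
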