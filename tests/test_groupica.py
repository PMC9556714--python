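"""Group ICA: PCA compression, Infomax unmixing, back-reconstruction,
back-projection and power bookkeeping."""

import functools

import numpy as np
import pytest

from wmgating import groupica as gi
from wmgating import synthdata as sd
from wmgating.preprocess import EpochSet


def whiten_unmix(comp, w):
    """Effective channel-space unmixing of a PCA+ICA chain."""
    scale = np.where(comp.eigenvalues > 0, 1 / np.sqrt(comp.eigenvalues), 0.0)
    return w @ (scale[:, None] * comp.basis.T)


class TestPCA:
    def test_rank_deficient_data_fully_explained(self, rng):
        x = rng.normal(size=(3, 500))
        data = rng.normal(size=(20, 3)) @ x  # rank 3, 20 channels
        comp, red = gi.pca_compress(data, n_pc=10)
        assert comp.explained_fraction == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_noise_explained_fraction(self, rng):
        data = rng.normal(size=(60, 100000))
        with pytest.warns(UserWarning):
            comp, _ = gi.pca_compress(data, n_pc=20)
        assert abs(comp.explained_fraction - 20 / 60) < 0.05

    def test_matches_bruteforce_eigendecomposition(self, rng):
        data = rng.normal(size=(6, 400)) * np.linspace(1, 3, 6)[:, None]
        comp, red = gi.pca_compress(data, n_pc=4, var_threshold=0.0)
        xc = data - data.mean(axis=1, keepdims=True)
        evals = np.sort(np.linalg.eigvalsh(xc @ xc.T / (400 - 1)))[::-1]
        assert comp.explained_fraction == pytest.approx(
            evals[:4].sum() / evals.sum(), rel=1e-10
        )
        # whitened output has identity covariance
        cov = red @ red.T / (400 - 1)
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            gi.pca_compress(rng.normal(size=(4, 100)), n_pc=5)


class TestConcatenate:
    def test_offsets_and_roundtrip(self, rng):
        a = rng.normal(size=(3, 10))
        b = rng.normal(size=(3, 15))
        agg, offsets = gi.concatenate_subjects([a, b])
        assert agg.shape == (3, 25) and offsets == [0, 10]
        np.testing.assert_array_equal(agg[:, :10], a)
        np.testing.assert_array_equal(agg[:, 10:], b)

    def test_single_subject_identity(self, rng):
        a = rng.normal(size=(2, 9))
        agg, offsets = gi.concatenate_subjects([a])
        np.testing.assert_array_equal(agg, a)
        assert offsets == [0]

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gi.concatenate_subjects([rng.normal(size=(2, 5)), rng.normal(size=(3, 5))])


class TestInfomax:
    def test_recovers_laplace_mixture(self, laplace_mixture):
        x, mixing, _ = laplace_mixture
        comp, red = gi.pca_compress(x, n_pc=4, var_threshold=0.0)
        w = gi.infomax(red, seed=1)
        assert gi.amari_index(whiten_unmix(comp, w) @ mixing) < 0.05

    def test_independent_input_gives_signed_permutation(self, rng):
        s = rng.laplace(size=(4, 20000))
        s = (s - s.mean(axis=1, keepdims=True)) / s.std(axis=1, keepdims=True)
        w = gi.infomax(s, seed=2)
        assert gi.amari_index(w) < 0.05

    def test_gaussian_sources_decorrelated_output(self, rng):
        s = rng.normal(size=(2, 30000))
        x = rng.normal(size=(2, 2)) @ s
        comp, red = gi.pca_compress(x, n_pc=2, var_threshold=0.0)
        w = gi.infomax(red, seed=3)
        out = w @ red
        r = np.corrcoef(out)[0, 1]
        assert abs(r) < 0.05

    def test_nonfinite_input_rejected(self):
        bad = np.zeros((2, 100))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            gi.infomax(bad)


@functools.lru_cache(maxsize=4)
def _fit_small_group(n_subjects=3, noise=0.05):
    """Tiny two-source cohort for back-projection identities (cached:
    tests only read from the fitted result)."""
    sources = sd.default_sources(
        8, rng=np.random.default_rng(42), effect_amplitude=10.0, base_amplitude=6.0
    )
    cfg = sd.SimConfig(
        n_subjects=n_subjects,
        n_channels=8,
        fs=128.0,
        epoch_window=(-200.0, 800.0),
        n_blocks=2,
        trials_per_block=20,
        sources=sources,
        noise_sd=noise,
        seed=9,
    )
    epochs = []
    for s in range(n_subjects):
        trials = sd.generate_trial_sequence(cfg, np.random.default_rng([9, s]))
        ep, _ = sd.simulate_epochs(trials, cfg, np.random.default_rng([10, s]), subject=f"S{s}")
        epochs.append(ep)
    topos = np.array([s.topography for s in sources])
    return gi.fit_groupica(epochs, n_pc=4, var_threshold=0.0, seed=0), epochs, topos


class TestBackProjection:
    def test_full_subset_reproduces_pca_retained_part(self, rng):
        res, epochs, _ = _fit_small_group()
        for si, ep in enumerate(epochs):
            x = ep.data.transpose(1, 0, 2).reshape(ep.n_channels, -1)
            xc = x - res.pca[si].mean[:, None]
            retained = res.pca[si].basis @ (res.pca[si].basis.T @ xc)
            xhat = gi.back_project(res, range(4), si)
            resid = np.linalg.norm(xhat - retained) / np.linalg.norm(retained)
            assert resid < 1e-6

    def test_subsets_add_linearly(self, rng):
        res, _, _ = _fit_small_group()
        full = gi.back_project(res, [0, 1, 2, 3], 0)
        parts = gi.back_project(res, [0, 2], 0) + gi.back_project(res, [1, 3], 0)
        np.testing.assert_allclose(parts, full, atol=1e-9)

    def test_concatenated_back_reconstructions_equal_aggregate_unmixing(self, rng):
        res, _, _ = _fit_small_group()
        # C = W X holds at the aggregate level
        agg = np.concatenate([res.A @ s for s in res.subject_sources], axis=1)
        np.testing.assert_allclose(
            np.concatenate(res.subject_sources, axis=1), res.W @ agg, atol=1e-8
        )

    def test_unknown_component_rejected(self, rng):
        res, _, _ = _fit_small_group()
        with pytest.raises(IndexError):
            gi.back_project(res, [7], 0)

    def test_single_planted_source_reproduced_without_noise(self, rng):
        src = sd.default_sources(8, rng=np.random.default_rng(3))[0]
        cfg = sd.SimConfig(
            n_channels=8, fs=128.0, epoch_window=(-200.0, 800.0),
            n_blocks=2, trials_per_block=20, sources=[src], noise_sd=0.0, seed=5,
        )
        trials = sd.generate_trial_sequence(cfg)
        ep, _ = sd.simulate_epochs(trials, cfg)
        res = gi.fit_groupica([ep], n_pc=2, var_threshold=0.0, seed=0)
        x = ep.data.transpose(1, 0, 2).reshape(8, -1)
        xhat = gi.back_project(res, [0, 1], 0, add_mean=True)
        rms = np.linalg.norm(xhat - x) / np.linalg.norm(x)
        assert rms < 0.01


class TestPpaf:
    def test_empty_subset_zero_full_subset_hundred(self, rng):
        res, epochs, _ = _fit_small_group()
        x = epochs[0].data.transpose(1, 0, 2).reshape(8, -1)
        assert gi.ppaf(res, [], 0, x) == pytest.approx(0.0, abs=1e-9)
        # rank of the centered data exceeds n_pc=4 here, so use the
        # retained part itself as the reference for the 100% identity
        xc = x - res.pca[0].mean[:, None]
        retained = res.pca[0].basis @ (res.pca[0].basis.T @ xc)
        full = gi.ppaf(res, range(4), 0, retained + res.pca[0].mean[:, None])
        assert full == pytest.approx(100.0, abs=1e-6)

    def test_matches_bruteforce_residual_power(self, rng):
        res, epochs, _ = _fit_small_group()
        x = epochs[1].data.transpose(1, 0, 2).reshape(8, -1)
        xc = x - res.pca[1].mean[:, None]
        for subset in ([0], [1, 3], [0, 1, 2]):
            xhat = res.subject_topographies[1][:, subset] @ res.subject_sources[1][subset, :]
            expected = 100.0 * (1 - ((xc - xhat) ** 2).sum() / (xc**2).sum())
            assert gi.ppaf(res, subset, 1, x) == pytest.approx(expected, rel=1e-10)

    def test_zero_power_rejected(self, rng):
        res, _, _ = _fit_small_group()
        zero = np.tile(res.pca[0].mean[:, None], (1, 10))
        with pytest.raises(ValueError):
            gi.ppaf(res, [0], 0, zero)


def test_end_to_end_topography_recovery():
    """Well-separated super-Gaussian sources at high SNR: group
    topographies match the planted ones after sign alignment."""
    res, _, topos = _fit_small_group(noise=0.2)
    g = res.topographies / np.linalg.norm(res.topographies, axis=0)
    for t in topos:
        cos = np.abs((t / np.linalg.norm(t)) @ g)
        assert cos.max() > 0.9


def test_amari_index_properties(rng):
    p = np.eye(5)[rng.permutation(5)] * rng.choice([-2.0, 3.0], size=5)
    assert gi.amari_index(p) == pytest.approx(0.0, abs=1e-12)
    assert gi.amari_index(np.ones((5, 5))) > 0.5


def test_reproducible_under_seed():
    res1, _, _ = _fit_small_group.__wrapped__()
    res2, _, _ = _fit_small_group.__wrapped__()
    np.testing.assert_array_equal(res1.W, res2.W)
    np.testing.assert_array_equal(res1.topographies, res2.topographies)
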