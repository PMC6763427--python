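"""Infomax ICA, two-stage reduction, back-reconstruction and selection."""

import warnings

import numpy as np
import pytest
from scipy import stats

from eicapvt import synthetic as syn
from eicapvt.fir import BIN_TIMES_S, DeconvMaps
from eicapvt.ica import (
    GroupEICA,
    InfomaxICA,
    TwoStagePca,
    match_components,
    select_components,
    stack_datasets,
    zscore_and_threshold,
)


def _super_gaussian_mixture(n_sources=3, n_samples=5000, seed=0):
    rng = np.random.default_rng(seed)
    S = rng.laplace(size=(n_sources, n_samples))
    A = rng.normal(size=(n_sources, n_sources))
    return S, A, (A @ S).T


class TestInfomax:
    def test_blind_source_recovery(self):
        S, A, X = _super_gaussian_mixture()
        ica = InfomaxICA(n_components=3, random_state=0).fit(X)
        S_est = ica.transform(X).T
        corr = np.abs(np.corrcoef(np.vstack([S, S_est]))[:3, 3:])
        # each true source matched by some component up to sign/permutation
        assert np.all(corr.max(axis=1) > 0.95)

    def test_deterministic_under_seed(self):
        _, _, X = _super_gaussian_mixture(seed=4)
        a = InfomaxICA(n_components=3, random_state=7).fit(X)
        b = InfomaxICA(n_components=3, random_state=7).fit(X)
        np.testing.assert_array_equal(a.components_, b.components_)

    def test_single_component_is_dominant_direction(self):
        rng = np.random.default_rng(2)
        s = rng.laplace(size=4000)
        direction = np.array([0.8, 0.6])
        X = np.outer(s, direction) + rng.normal(scale=0.01, size=(4000, 2))
        ica = InfomaxICA(n_components=1, random_state=0).fit(X)
        u, _, _ = np.linalg.svd(X - X.mean(0), full_matrices=False)
        w = ica.mixing_[:, 0] / np.linalg.norm(ica.mixing_[:, 0])
        assert abs(np.dot(w, direction)) > 0.999

    def test_sources_decorrelated(self):
        _, _, X = _super_gaussian_mixture(seed=9)
        ica = InfomaxICA(n_components=3, random_state=0).fit(X)
        S_est = ica.transform(X)
        C = np.corrcoef(S_est.T)
        off = C[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_too_many_components_raises(self):
        X = np.random.default_rng(0).normal(size=(50, 4))
        with pytest.raises(ValueError):
            InfomaxICA(n_components=5).fit(X)


def _fake_maps(n_datasets=6, shape=(6, 6, 4), seed=0, noise=0.02):
    """DeconvMaps built from two blob networks with distinct time courses."""
    rng = np.random.default_rng(seed)
    amp = {("normal", "HS"): 1.0}
    n1 = syn.gaussian_blob_network(shape, [(1.5, 1.5, 1.5)], sigma_vox=0.9,
                                   name="a", amp=amp)
    n2 = syn.gaussian_blob_network(shape, [(4.5, 4.5, 2.5)], sigma_vox=0.9,
                                   name="b", amp=amp)
    maps = np.stack([n1.spatial_map.reshape(-1), n2.spatial_map.reshape(-1)])
    t1 = np.concatenate([syn.double_gamma(BIN_TIMES_S, peak_delay=5.0)] * 2)
    t2 = np.concatenate([syn.double_gamma(BIN_TIMES_S, peak_delay=8.0,
                                          dispersion=1.4)] * 2)
    T = np.stack([t1, t2])
    out = []
    for i in range(n_datasets):
        X = T.T @ maps + rng.normal(size=(48, maps.shape[1])) * noise
        out.append(
            DeconvMaps(maps=X.reshape(48, *shape), bin_times=BIN_TIMES_S,
                       classes=("normal", "lapse"), subject=f"sub-{i // 2:02d}",
                       condition="SS" if i % 2 == 0 else "HS")
        )
    return out, maps


class TestStacking:
    def test_study_scale_yields_66_datasets(self):
        maps, _ = _fake_maps(n_datasets=66, noise=0.01)
        data, mask, index = stack_datasets(maps)
        assert data.shape[0] == 66  # 33 subjects x 2 conditions
        assert data.shape[1] == 48
        assert index["subject"].nunique() == 33

    def test_single_dataset_passthrough(self):
        maps, _ = _fake_maps(n_datasets=1)
        data, mask, _ = stack_datasets(maps)
        np.testing.assert_allclose(
            data[0], maps[0].maps.reshape(48, -1)[:, mask]
        )

    def test_grid_mismatch_raises(self):
        a, _ = _fake_maps(n_datasets=1, shape=(6, 6, 4))
        b, _ = _fake_maps(n_datasets=1, shape=(6, 6, 5))
        with pytest.raises(ValueError, match="grid"):
            stack_datasets(a + b)


class TestTwoStagePca:
    def test_full_rank_reduction_is_lossless(self):
        # mean-image removal drops one rank, so full rank is T - 1
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 10, 200))
        pca = TwoStagePca(dataset_dims=9, group_dims=18)
        pca.fit_transform(data)
        for i in range(2):
            Xc = data[i] - data[i].mean(axis=0)
            recon = pca.basis_[i] @ pca.basis_[i].T @ Xc
            np.testing.assert_allclose(recon, Xc, atol=1e-10)

    def test_truncation_error_matches_svd_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 300))
        Xc = X - X.mean(axis=0)
        pca = TwoStagePca(dataset_dims=6, group_dims=6)
        pca.fit_transform(X[None])
        recon = pca.basis_[0] @ pca.basis_[0].T @ Xc
        err = np.linalg.norm(Xc - recon) ** 2
        s = np.linalg.svd(Xc, compute_uv=False)
        assert err == pytest.approx(s[6] ** 2, rel=1e-8)

    def test_duplicated_dataset_reduces_identically(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 100))
        pca = TwoStagePca(dataset_dims=5, group_dims=5)
        pca.fit_transform(np.stack([X, X]))
        np.testing.assert_allclose(pca.reduced_[0], pca.reduced_[1],
                                   atol=1e-10)

    def test_rank_overflow_raises(self):
        data = np.zeros((1, 5, 50))
        data[0, 0] = 1.0
        with pytest.raises(ValueError):
            TwoStagePca(dataset_dims=5, group_dims=5).fit_transform(data)


@pytest.fixture(scope="module")
def fitted():
    maps, truth = _fake_maps(n_datasets=8, noise=0.02)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GroupEICA(n_components=2, dataset_dims=8,
                          random_state=0).fit(maps)
    return model, truth


class TestGroupEICA:
    def test_recovers_injected_networks(self, fitted):
        model, truth = fitted
        _, corrs = match_components(model.group_maps_, truth[:, model.mask_])
        assert np.all(corrs > 0.95)

    def test_sign_convention_max_weight_positive(self, fitted):
        model, _ = fitted
        for c in range(model.n_components):
            v = np.argmax(np.abs(model.group_maps_[c]))
            assert model.group_maps_[c][v] > 0

    def test_back_reconstruction_identity(self, fitted):
        model, _ = fitted
        # mixing x sources reproduces the reduced data (voxel-centered)
        Y = model.pca_.group_op_ @ np.concatenate(model.pca_.reduced_, axis=0)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        recon = model.mixing_ @ model.group_maps_
        resid = np.linalg.norm(Yc - recon) / np.linalg.norm(Yc)
        assert resid < 1e-6

    def test_timecourse_structure(self, fitted):
        model, _ = fitted
        assert model.timecourses_.shape[1] == 48
        maps_i, tc_i = model.back_reconstruct(0)
        np.testing.assert_array_equal(tc_i, model.timecourses_[0])
        with pytest.raises(KeyError):
            model.back_reconstruct(99)

    def test_group_of_one_reproduces_single_dataset_ica(self):
        maps, truth = _fake_maps(n_datasets=1, noise=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = GroupEICA(n_components=2, dataset_dims=6,
                              random_state=0).fit(maps)
        _, corrs = match_components(model.group_maps_, truth[:, model.mask_])
        assert np.all(corrs > 0.9)
        # back-reconstructed dataset map equals the group map (one dataset)
        for c in range(2):
            r = np.corrcoef(model.dataset_maps_[0, c], model.group_maps_[c])[0, 1]
            assert abs(r) > 0.999

    def test_dataset_shuffle_permutes_outputs(self):
        maps, truth = _fake_maps(n_datasets=8, noise=0.01)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = GroupEICA(n_components=2, dataset_dims=8, random_state=0).fit(maps)
            b = GroupEICA(n_components=2, dataset_dims=8, random_state=0).fit(
                maps[::-1]
            )
        # group maps agree up to component permutation/sign
        assign, corrs = match_components(a.group_maps_, b.group_maps_)
        assert np.all(corrs > 0.99)
        # dataset outputs permuted identically with the shuffle
        tc_a = a.timecourses_[0, :, :]
        tc_b = b.timecourses_[-1, :, assign].T
        for c in range(2):
            assert abs(np.corrcoef(tc_a[:, assign[c]], tc_b[:, assign[c]])[0, 1]) > 0.99


class TestZMapsAndSelection:
    def test_extreme_voxel_in_support(self):
        m = np.zeros(500)
        m[123] = 10.0
        z = zscore_and_threshold(m)
        assert z.support[123]
        assert z.zmap.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.zmap.std() == pytest.approx(1.0)

    def test_random_map_support_fraction_matches_normal_tail(self):
        rng = np.random.default_rng(0)
        z = zscore_and_threshold(rng.standard_normal(200_000))
        expected = stats.norm.sf(1.5)  # ~0.0668
        assert z.support.mean() == pytest.approx(expected, abs=0.005)

    def test_thresholding_idempotent_on_support(self):
        rng = np.random.default_rng(1)
        z1 = zscore_and_threshold(rng.standard_normal(10_000))
        z2 = zscore_and_threshold(z1.zmap)
        np.testing.assert_array_equal(z1.support, z2.support)

    def test_constant_map_raises(self):
        with pytest.raises(ValueError):
            zscore_and_threshold(np.ones(100))

@pytest.fixture(scope="module")
def model_with_artifact():
    shape = (6, 6, 4)
    rng = np.random.default_rng(5)
    amp = {("normal", "HS"): 1.0}
    net = syn.gaussian_blob_network(shape, [(3, 3, 2)], sigma_vox=0.9,
                                    name="net", amp=amp)
    rim = np.ones(shape)
    rim[1:-1, 1:-1, 1:-1] = 0.0  # pure periphery pattern
    maps_list = []
    t_net = np.concatenate([syn.double_gamma(BIN_TIMES_S)] * 2)
    t_rim = rng.normal(size=48)  # erratic, event-unlocked
    for i in range(8):
        X = (np.outer(t_net, net.spatial_map.reshape(-1))
             + np.outer(t_rim * rng.normal(), rim.reshape(-1))
             + rng.normal(size=(48, rim.size)) * 0.02)
        maps_list.append(
            DeconvMaps(maps=X.reshape(48, *shape), bin_times=BIN_TIMES_S,
                       classes=("normal", "lapse"),
                       subject=f"sub-{i // 2:02d}",
                       condition="SS" if i % 2 == 0 else "HS")
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GroupEICA(n_components=2, dataset_dims=8,
                          random_state=0).fit(maps_list)
    return model, net, rim.astype(bool)


class TestSelection:
    def test_rim_artifact_rejected_network_retained(self, model_with_artifact):
        model, net, rim = model_with_artifact
        sel = select_components(model, rim)
        assign, corrs = match_components(
            model.group_maps_, net.spatial_map.reshape(-1)[model.mask_][None]
        )
        net_comp = int(assign[0])
        assert net_comp in sel.retained
        other = 1 - net_comp
        assert other in sel.rejected

    def test_override_forces_retention(self, model_with_artifact):
        model, _, rim = model_with_artifact
        sel = select_components(model, rim, force_retain=(0, 1))
        assert sorted(sel.retained) == [0, 1]
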