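import numpy as np
import pytest

from visrsa.ceiling import lower_bound, upper_bound
from visrsa.geometry import compare_rdms
from visrsa.pipeline import batch_compare_rdvs
from visrsa.simulate import (SimulationConfig, default_planted_mapping,
                             generate_brain_data, generate_ground_truth,
                             generate_model_layers, selectivity_spec)
from visrsa.voxels import flag_category_selective, split_half_reliability


def tiny_config(**kw):
    base = dict(n_subjects=3, n_regions=4, n_categories=8, n_runs=6,
                n_voxels_per_region=40, n_model_layers=6,
                n_latent_features=20, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_default_mapping_is_evenly_spaced(self):
        assert default_planted_mapping(6, 11) == (1, 3, 5, 7, 9, 11)
        assert default_planted_mapping(6, 6) == (1, 2, 3, 4, 5, 6)

    def test_mapping_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_regions=2, n_model_layers=4, planted_mapping=(1, 9))
        with pytest.raises(ValueError):
            SimulationConfig(n_regions=3, planted_mapping=(1, 2))

    def test_region_names(self):
        assert SimulationConfig().region_names == ["V1", "V2", "V3", "V4",
                                                   "LOT", "VOT"]


class TestGroundTruth:
    def test_deterministic(self):
        a = generate_ground_truth(tiny_config())
        b = generate_ground_truth(tiny_config())
        np.testing.assert_array_equal(a.level_features, b.level_features)
        np.testing.assert_array_equal(a.layer_rdvs, b.layer_rdvs)

    def test_seed_changes_output(self):
        a = generate_ground_truth(tiny_config(seed=1))
        b = generate_ground_truth(tiny_config(seed=2))
        assert not np.allclose(a.level_features, b.level_features)

    def test_degenerate_chain_identical_rdms(self):
        truth = generate_ground_truth(tiny_config(level_mixing=1.0, exemplar_sd=0.0))
        for l in range(1, truth.layer_rdvs.shape[0]):
            np.testing.assert_allclose(truth.layer_rdvs[l], truth.layer_rdvs[0],
                                       atol=1e-10)

    def test_level_similarity_decays_with_distance(self):
        truth = generate_ground_truth(tiny_config(n_model_layers=8, seed=3))
        sims = batch_compare_rdvs(truth.layer_rdvs, truth.layer_rdvs, "pearson")
        L = sims.shape[0]
        near = np.mean([sims[i, i + 1] for i in range(L - 1)])
        far = np.mean([sims[i, j] for i in range(L) for j in range(L)
                       if abs(i - j) >= L - 2])
        mid = np.mean([sims[i, j] for i in range(L) for j in range(L)
                       if abs(i - j) == 3])
        assert near > mid > far

    def test_region_rdvs_follow_mapping(self):
        truth = generate_ground_truth(tiny_config())
        for r, layer in enumerate(truth.region_layer_mapping):
            np.testing.assert_array_equal(truth.region_rdvs[r],
                                          truth.layer_rdvs[layer - 1])


class TestBrainData:
    def test_deterministic(self):
        cfg = tiny_config()
        truth = generate_ground_truth(cfg)
        a = generate_brain_data(truth)
        b = generate_brain_data(truth)
        np.testing.assert_array_equal(a.data[0][0].betas, b.data[0][0].betas)

    def test_adding_subjects_preserves_existing(self):
        cfg3 = tiny_config(n_subjects=3)
        cfg5 = tiny_config(n_subjects=5)
        a = generate_brain_data(generate_ground_truth(cfg3))
        b = generate_brain_data(generate_ground_truth(cfg5))
        for s in range(3):
            for r in range(cfg3.n_regions):
                np.testing.assert_array_equal(a.data[s][r].betas, b.data[s][r].betas)

    def test_noise_free_reliability_one(self):
        cfg = tiny_config(run_noise_sd=0.0)
        dataset = generate_brain_data(generate_ground_truth(cfg))
        rel = split_half_reliability(dataset.data[0][0])
        np.testing.assert_allclose(rel, 1.0, atol=1e-12)

    def test_noise_free_identical_subjects_ceiling_one(self):
        cfg = tiny_config(run_noise_sd=0.0, subject_loading_sd=0.0)
        dataset = generate_brain_data(generate_ground_truth(cfg))
        from visrsa.geometry import ResponseMatrix, build_rdm, vectorize_rdm
        vecs = []
        for s in range(cfg.n_subjects):
            series = dataset.data[s][0]
            rm = ResponseMatrix(series.betas.mean(axis=0),
                                series.condition_labels)
            vecs.append(vectorize_rdm(build_rdm(rm)))
        np.testing.assert_array_equal(vecs[0], vecs[1])
        assert lower_bound(vecs) == pytest.approx(1.0)
        assert upper_bound(vecs) == pytest.approx(1.0)

    def test_signal_voxel_subset(self):
        cfg = tiny_config(n_signal_voxels_per_region=10, run_noise_sd=0.0)
        truth = generate_ground_truth(cfg)
        dataset = generate_brain_data(truth)
        betas = dataset.data[0][0].betas
        signal = truth.signal_voxels[0]
        assert signal.size == 10
        noise_voxels = np.setdiff1d(np.arange(cfg.n_voxels_per_region), signal)
        np.testing.assert_array_equal(betas[:, :, noise_voxels], 0.0)
        assert np.abs(betas[:, :, signal]).sum() > 0

    def test_inter_subject_rdm_correlation_in_monte_carlo_band(self):
        # mean pairwise subject RDM correlation matches an independent
        # re-simulation with the same parameters (different seeds)
        def mean_pairwise(seed):
            cfg = tiny_config(seed=seed, n_subjects=4)
            dataset = generate_brain_data(generate_ground_truth(cfg))
            from visrsa.pipeline import subject_region_rdvs
            rdvs, _ = subject_region_rdvs(dataset, top_k=30)
            rs = []
            for r in range(cfg.n_regions):
                for i in range(4):
                    for j in range(i + 1, 4):
                        rs.append(compare_rdms(rdvs[i, r], rdvs[j, r]))
            return np.mean(rs)

        observed = mean_pairwise(0)
        replicates = np.array([mean_pairwise(s) for s in range(1, 13)])
        lo = replicates.mean() - 3 * replicates.std(ddof=1)
        hi = replicates.mean() + 3 * replicates.std(ddof=1)
        assert lo < observed < hi


class TestModelLayers:
    def test_planted_realizes_levels(self):
        cfg = tiny_config()
        truth = generate_ground_truth(cfg)
        layers = generate_model_layers(truth, mode="planted")
        assert len(layers) == cfg.n_model_layers
        np.testing.assert_array_equal(layers[2].values, truth.level_features[2])

    def test_matched_layer_reproduces_region_geometry(self):
        cfg = tiny_config(run_noise_sd=0.0, subject_loading_sd=0.0)
        truth = generate_ground_truth(cfg)
        dataset = generate_brain_data(truth)
        layers = generate_model_layers(truth, mode="matched")
        region = cfg.matched_region % cfg.n_regions
        layer_ix = truth.region_layer_mapping[region] - 1
        from visrsa.geometry import ResponseMatrix, build_rdm, vectorize_rdm
        lvec = vectorize_rdm(build_rdm(layers[layer_ix]))
        series = dataset.data[0][region]
        bvec = vectorize_rdm(build_rdm(ResponseMatrix(
            series.betas.mean(axis=0), series.condition_labels)))
        np.testing.assert_allclose(lvec, bvec, atol=1e-10)
        assert compare_rdms(lvec, bvec) == pytest.approx(1.0)

    def test_null_independent_of_truth(self):
        cfg = tiny_config()
        truth = generate_ground_truth(cfg)
        layers = generate_model_layers(truth, mode="null")
        from visrsa.pipeline import layer_rdvs
        null_rdvs = layer_rdvs(layers)
        rs = batch_compare_rdvs(truth.region_rdvs, null_rdvs, "spearman")
        assert np.abs(rs.mean()) < 0.15  # zero within Monte-Carlo error

    def test_unknown_mode(self):
        truth = generate_ground_truth(tiny_config())
        with pytest.raises(ValueError):
            generate_model_layers(truth, mode="bogus")


class TestSelectiveVoxels:
    def test_planted_voxels_flagged(self):
        cfg = tiny_config(n_subjects=2, n_runs=16, run_noise_sd=1.0,
                          n_voxels_per_region=120,
                          selective_voxel_fraction=0.1, selective_offset=6.0)
        truth = generate_ground_truth(cfg)
        dataset = generate_brain_data(truth)
        spec = selectivity_spec(cfg)
        hits = total = 0
        for s in range(cfg.n_subjects):
            for region in (cfg.n_regions - 2, cfg.n_regions - 1):
                planted = np.concatenate(
                    list(truth.selective_voxels[region].values()))
                assert planted.size > 0
                mask = flag_category_selective(dataset.data[s][region], spec)
                hits += mask[planted].sum()
                total += planted.size
        assert hits / total >= 0.95

    def test_no_planting_in_early_regions(self):
        cfg = tiny_config(selective_voxel_fraction=0.1, selective_offset=5.0)
        truth = generate_ground_truth(cfg)
        assert truth.selective_voxels[0] == {}
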