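from collections import deque

import numpy as np
import pandas as pd
import pytest

from itcmed.mediation import (InvalidConstraintError, MediationConfig,
                              SIGNS_DISCOUNT_RATE, SIGNS_SENSITIVITY,
                              bh_threshold, bootstrap_mediation, conjunction,
                              extract_clusters, fdr_across_paths,
                              fit_voxel_mediation, run_whole_brain)
from itcmed.volumes import Region, VolumeSpec, simulate_gmd_volumes


def _oracle_ols(X, y):
    X = np.asarray(X, float)
    return np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))


class TestVoxelFit:
    def test_noiseless_chain(self):
        # Y depends on X only through M; a whisper of independent variation
        # in M keeps the b/c' split identifiable (M = 2X exactly would be
        # rank-deficient: the data cannot tell b=3,c'=0 from b=0,c'=6)
        rng = np.random.default_rng(10)
        X = np.repeat([0.0, 1.0], 10)
        M = 2 * X + 1e-5 * rng.standard_normal(20)
        Y = 3 * M
        res = fit_voxel_mediation(X, M, Y)
        assert res.a == pytest.approx(2.0, abs=1e-4)
        assert res.b == pytest.approx(3.0, abs=1e-4)
        assert res.ab == pytest.approx(6.0, abs=1e-3)
        assert res.c == pytest.approx(6.0, abs=1e-4)
        assert res.c_prime == pytest.approx(0.0, abs=1e-3)

    def test_collinear_mediator_marked_invalid(self):
        X = np.repeat([0.0, 1.0], 10)
        res = fit_voxel_mediation(X, 2 * X, 6 * X)
        assert res.a == pytest.approx(2.0, abs=1e-10)
        assert np.isnan(res.b) and np.isnan(res.ab)

    def test_decomposition_identity_and_oracle(self):
        rng = np.random.default_rng(0)
        X = np.repeat([0.0, 1.0], 25)
        M = -0.5 * X + rng.standard_normal(50)
        Y = 0.3 * X + 0.8 * M + rng.standard_normal(50)
        res = fit_voxel_mediation(X, M, Y)
        assert res.ab == pytest.approx(res.c - res.c_prime, abs=1e-10)
        Z = np.column_stack([np.ones(50), X])
        assert res.a == pytest.approx(_oracle_ols(Z, M)[1], abs=1e-8)
        full = np.column_stack([Z, M])
        ref = _oracle_ols(full, Y)
        assert res.c_prime == pytest.approx(ref[1], abs=1e-8)
        assert res.b == pytest.approx(ref[2], abs=1e-8)
        assert res.c == pytest.approx(_oracle_ols(Z, Y)[1], abs=1e-8)

    def test_covariates_enter_all_paths(self):
        rng = np.random.default_rng(1)
        X = np.repeat([0.0, 1.0], 30)
        age = rng.uniform(50, 80, 60)
        M = -0.4 * X + 0.01 * age + rng.standard_normal(60) * 0.3
        Y = 0.2 * X + 0.5 * M - 0.02 * age + rng.standard_normal(60) * 0.3
        res = fit_voxel_mediation(X, M, Y, covariates=age)
        # identity survives when the same covariates enter all three models
        assert res.ab == pytest.approx(res.c - res.c_prime, abs=1e-10)
        Z = np.column_stack([np.ones(60), X, age])
        assert res.a == pytest.approx(_oracle_ols(Z, M)[1], abs=1e-8)

    def test_too_few_participants(self):
        with pytest.raises(ValueError):
            fit_voxel_mediation([0, 1] * 4, np.arange(8.0), np.arange(8.0))


class TestBootstrap:
    def test_strong_mediation_hits_p_floor(self):
        rng = np.random.default_rng(2)
        X = np.repeat([0.0, 1.0], 40)
        M = -1.0 * X + 0.05 * rng.standard_normal(80)
        Y = 2.0 * M + 0.05 * rng.standard_normal(80)
        p = bootstrap_mediation(X, M, Y, n_boot=1000, seed=0)
        assert p["p_ab"][0] == pytest.approx(2 / 1000)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        X = np.repeat([0.0, 1.0], 20)
        M = rng.standard_normal((40, 5))
        Y = rng.standard_normal(40)
        p1 = bootstrap_mediation(X, M, Y, n_boot=1000, seed=42)
        p2 = bootstrap_mediation(X, M, Y, n_boot=1000, seed=42)
        for k in p1:
            assert np.array_equal(p1[k], p2[k])

    def test_chunking_does_not_change_results(self):
        rng = np.random.default_rng(4)
        X = np.repeat([0.0, 1.0], 20)
        M = rng.standard_normal((40, 4))
        Y = rng.standard_normal(40)
        p1 = bootstrap_mediation(X, M, Y, n_boot=1000, seed=9, chunk=64)
        p2 = bootstrap_mediation(X, M, Y, n_boot=1000, seed=9, chunk=1000)
        for k in p1:
            assert np.array_equal(p1[k], p2[k])

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_mediation(np.repeat([0.0, 1.0], 10),
                                np.arange(20.0), np.arange(20.0), n_boot=100)


class TestFDR:
    def test_uniformly_small_p_all_pass(self):
        mask = np.ones((3, 3, 3), bool)
        maps = {k: np.full((3, 3, 3), 0.001) for k in ("a", "b", "ab")}
        masks, cutoff = fdr_across_paths(maps, mask, q=0.05)
        for k in masks:
            assert masks[k].all()

    def test_hand_computed_bh_example(self):
        # pooled p = {0.01..0.05}: BH thresholds i*q/m meet every p exactly
        assert bh_threshold(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), 0.05) == 0.05
        # only the first survives once the rest are far above their ranks
        assert bh_threshold(np.array([0.001, 0.4, 0.5, 0.6, 0.7]), 0.05) == 0.001
        assert bh_threshold(np.array([0.9, 0.95]), 0.05) == 0.0

    def test_pooled_cutoff_shared_across_paths(self):
        rng = np.random.default_rng(5)
        mask = np.ones((4, 4, 4), bool)
        maps = {k: rng.random((4, 4, 4)) for k in ("a", "b", "ab")}
        maps["a"][0, 0, 0] = 1e-6
        masks, cutoff = fdr_across_paths(maps, mask, q=0.05)
        for k in masks:
            assert np.array_equal(masks[k], maps[k] <= cutoff)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fdr_across_paths({k: np.ones((2, 2, 2)) for k in ("a", "b", "ab")},
                             np.zeros((2, 2, 2), bool))


class TestConjunction:
    def _maps(self, shape=(4, 4, 4)):
        coef = {"a": -np.ones(shape), "b": -np.ones(shape), "ab": np.ones(shape)}
        return coef

    def test_disjoint_masks_empty(self):
        shape = (4, 4, 4)
        masks = {"a": np.zeros(shape, bool), "b": np.zeros(shape, bool),
                 "ab": np.zeros(shape, bool)}
        masks["a"][0], masks["b"][1], masks["ab"][2] = True, True, True
        out = conjunction(masks, SIGNS_DISCOUNT_RATE, self._maps())
        assert not out.any()

    def test_identical_masks_with_matching_signs(self):
        shape = (4, 4, 4)
        m = np.ones(shape, bool)
        out = conjunction({"a": m, "b": m, "ab": m}, SIGNS_DISCOUNT_RATE,
                          self._maps())
        assert out.all()

    def test_sign_mismatch_excluded(self):
        shape = (4, 4, 4)
        m = np.ones(shape, bool)
        coef = self._maps()
        coef["b"][0] = +1  # wrong direction for the discount-rate conjunction
        out = conjunction({"a": m, "b": m, "ab": m}, SIGNS_DISCOUNT_RATE, coef)
        assert not out[0].any() and out[1:].all()

    def test_inconsistent_sign_spec_rejected(self):
        m = np.ones((2, 2, 2), bool)
        with pytest.raises(InvalidConstraintError):
            conjunction({"a": m, "b": m, "ab": m}, {"a": -1, "b": -1, "ab": -1},
                        self._maps((2, 2, 2)))


def _flood_fill_components(mask):
    """Independent 26-connectivity labelling by BFS."""
    labels = np.zeros(mask.shape, int)
    current = 0
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    for idx in np.argwhere(mask):
        if labels[tuple(idx)]:
            continue
        current += 1
        queue = deque([tuple(idx)])
        labels[tuple(idx)] = current
        while queue:
            p = queue.popleft()
            for off in offsets:
                q = tuple(np.array(p) + off)
                if all(0 <= qi < s for qi, s in zip(q, mask.shape)) \
                        and mask[q] and not labels[q]:
                    labels[q] = current
                    queue.append(q)
    return labels


class TestClusters:
    def test_two_separated_blocks(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[1:4, 1:4, 1:4] = True
        mask[6:9, 6:9, 6:9] = True
        tab = extract_clusters(mask, np.ones(mask.shape), min_size=5)
        assert len(tab) == 2
        assert set(tab["size"]) == {27}

    def test_min_size_filter(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        assert len(extract_clusters(mask, np.ones(mask.shape), min_size=2)) == 0
        assert len(extract_clusters(mask, np.ones(mask.shape), min_size=1)) == 1

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            mask = rng.random((8, 8, 8)) < 0.2
            ref = _flood_fill_components(mask)
            tab = extract_clusters(mask, rng.standard_normal(mask.shape),
                                   min_size=1)
            ref_sizes = sorted(np.bincount(ref.ravel())[1:].tolist())
            assert sorted(tab["size"].tolist()) == [s for s in ref_sizes if s]

    def test_peak_voxel_is_abs_max(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:4, 1:4, 1:4] = True
        coef = np.zeros(mask.shape)
        coef[mask] = 0.1
        coef[2, 3, 1] = -0.9
        tab = extract_clusters(mask, coef, min_size=1)
        assert (tab.loc[0, ["peak_x", "peak_y", "peak_z"]].tolist() == [2, 3, 1])
        assert tab.loc[0, "sign"] == -1


@pytest.fixture(scope="module")
def small_run():
    spec = VolumeSpec(shape=(10, 10, 10), mask_margin=2, regions=(
        Region("med", (3, 3, 3), (4, 4, 4), a=-0.08, b=-6.0),))
    part = pd.DataFrame({"participant_id": [f"S{i}" for i in range(80)],
                         "group": ["bvftd"] * 40 + ["control"] * 40})
    vols, y, truth = simulate_gmd_volumes(spec, part,
                                          rng=np.random.default_rng(0))
    X = (part["group"] == "bvftd").to_numpy(float)
    cfg = MediationConfig(n_boot=1000, seed=1)
    maps = run_whole_brain(vols, truth["mask"], X, y, config=cfg)
    return spec, vols, truth, X, y, cfg, maps


class TestWholeBrain:

    def test_all_in_mask_voxels_populated(self, small_run):
        _, _, truth, _, _, _, maps = small_run
        mask = truth["mask"]
        for name, arr in {**maps.coef, **maps.p}.items():
            n_finite = np.isfinite(arr[mask]).sum()
            assert n_finite == mask.sum() - maps.manifest["n_invalid_voxels"]
            assert not np.isfinite(arr[~mask]).any()

    def test_identity_everywhere(self, small_run):
        _, _, _, _, _, _, maps = small_run
        resid = maps.coef["ab"] - (maps.coef["c"] - maps.coef["c_prime"])
        assert np.nanmax(np.abs(resid)) < 1e-10

    def test_planted_region_positive_ab(self, small_run):
        spec, _, truth, _, _, _, maps = small_run
        med = truth["mediator"]
        assert np.nanmean(maps.coef["ab"][med] > 0) > 0.9

    def test_rerun_identical(self, small_run):
        spec, vols, truth, X, y, cfg, maps = small_run
        again = run_whole_brain(vols, truth["mask"], X, y, config=cfg)
        for k in maps.p:
            assert np.array_equal(maps.p[k], again.p[k], equal_nan=True)

    def test_missing_outcome_listwise_dropped(self, small_run):
        spec, vols, truth, X, y, cfg, _ = small_run
        y2 = y.copy()
        y2[:3] = np.nan
        maps = run_whole_brain(vols, truth["mask"], X, y2, config=cfg)
        assert maps.manifest["n_dropped"] == 3
        assert maps.manifest["n_participants"] == len(y) - 3

    def test_shape_mismatch_rejected(self, small_run):
        spec, vols, truth, X, y, cfg, _ = small_run
        with pytest.raises(ValueError):
            run_whole_brain(vols, np.ones((5, 5, 5), bool), X, y, config=cfg)
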