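"""Searchlight RSA: spheres, neural RDMs, rank correlation, group inference."""

import itertools

import numpy as np
import pytest
from scipy import stats

from votrsa import (
    RDM,
    SearchlightSpec,
    TrialBetaSeries,
    cluster_mean_representation,
    correlate_rdms,
    cross_region_correlation,
    dice_overlap,
    group_rsa_inference,
    neural_rdm_at,
    rdm_from_vector,
    searchlight_representation_map,
    sphere_offsets,
)
from votrsa.errors import ConfigurationError, InvalidRDMError, UndefinedCorrelationError
from votrsa.searchlight import RepresentationMap, spearman_rho
from votrsa import synthetic as syn


class TestSphereOffsets:
    def test_radius6_at_2mm_enumeration_oracle(self):
        offs = sphere_offsets(6.0, 2.0)
        oracle = {
            (i, j, k)
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if i * i + j * j + k * k <= 9
        }
        assert {tuple(o) for o in offs} == oracle
        assert len(offs) == 123

    def test_radius_below_voxel_size_single_voxel(self):
        with pytest.warns(UserWarning, match="single-voxel"):
            offs = sphere_offsets(1.5, 2.0)
        assert offs.shape == (1, 3)

    def test_symmetric_under_negation(self):
        offs = {tuple(o) for o in sphere_offsets(5.0, (2.0, 2.0, 3.0))}
        assert {(-i, -j, -k) for i, j, k in offs} == offs

    def test_anisotropic_voxels(self):
        offs = sphere_offsets(4.0, (2.0, 4.0, 4.0))
        mm = offs * np.array([2.0, 4.0, 4.0])
        assert (np.linalg.norm(mm, axis=1) <= 4.0 + 1e-9).all()


def _series(patterns, ids=None, affine=None):
    """(V, n) pattern matrix as a V x 1 x 1 x n series."""
    patterns = np.asarray(patterns, dtype=float)
    data = patterns[:, None, None, :]
    ids = ids or [f"s{i:02d}" for i in range(patterns.shape[1])]
    return TrialBetaSeries(data, ids, "RW", np.eye(4) if affine is None else affine)


class TestNeuralRDM:
    def test_identical_and_negated_patterns(self):
        p = np.array([[1.0, 1.0, -1.0], [2.0, 2.0, -2.0], [0.5, 0.5, -0.5]])
        series = _series(p)
        spec = SearchlightSpec(radius_mm=6.0, min_voxels=2)
        rdm = neural_rdm_at((1, 0, 0), series, spec, np.ones((3, 1, 1), bool))
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)  # r = 1
        assert rdm.values[0, 2] == pytest.approx(2.0, abs=1e-12)  # r = -1

    def test_matches_covariance_formula_oracle(self, rng):
        patterns = rng.normal(size=(5, 4))
        series = _series(patterns)
        spec = SearchlightSpec(min_voxels=2)
        rdm = neural_rdm_at((2, 0, 0), series, spec, np.ones((5, 1, 1), bool))
        for i in range(4):
            for j in range(i):
                xi, xj = patterns[:, i], patterns[:, j]
                r = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (
                    np.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                )
                assert rdm.values[i, j] == pytest.approx(1 - r, abs=1e-10)

    def test_constant_trial_pattern_gives_missing_cells(self):
        patterns = np.column_stack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2])
        rdm = neural_rdm_at(
            (3, 0, 0), _series(patterns), SearchlightSpec(min_voxels=2),
            np.ones((6, 1, 1), bool),
        )
        assert np.isnan(rdm.values[0, 1]) and np.isnan(rdm.values[0, 2])
        assert np.isfinite(rdm.values[1, 2])

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ConfigurationError, match="minimum"):
            neural_rdm_at(
                (0, 0, 0), _series(np.random.rand(2, 4)), SearchlightSpec(),
                np.ones((2, 1, 1), bool),
            )


class TestCorrelateRDMs:
    def _rdm(self, vec, labels=None, kind="neural"):
        n = int((1 + np.sqrt(1 + 8 * len(vec))) / 2)
        return rdm_from_vector(labels or [f"s{i}" for i in range(n)], vec, kind)

    def test_identical_rdms_clip_to_finite_z(self):
        a = self._rdm([0.1, 0.5, 0.9])
        z = correlate_rdms(a, a)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(0.999999))

    def test_rank_reversal_gives_negative(self):
        a = self._rdm([0.1, 0.5, 0.9, 0.3, 0.7, 0.2])
        b = self._rdm(1.0 - np.asarray([0.1, 0.5, 0.9, 0.3, 0.7, 0.2]))
        assert correlate_rdms(a, b) == pytest.approx(np.arctanh(-0.999999))

    def test_tied_ranks_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 1.5, 0.5])
        y = np.array([1.0, 3.0, 2.0, 4.0, 2.5, 0.1])
        rho = spearman_rho(x, y)
        # oracle: explicit average ranks then Pearson
        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            sv = v[order]
            i = 0
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks
        rx, ry = avg_ranks(x), avg_ranks(y)
        expect = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-12)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_fisher_z_strictly_increasing_and_clip_only_at_one(self):
        rhos = np.linspace(-0.99, 0.99, 21)
        zs = np.arctanh(rhos)
        assert (np.diff(zs) > 0).all()
        n = 5
        vec_m = np.linspace(0.1, 0.9, n * (n - 1) // 2)
        model = self._rdm(vec_m)
        swapped = vec_m.copy()
        swapped[[0, 1]] = swapped[[1, 0]]  # one rank inversion: |rho| < 1
        z = correlate_rdms(self._rdm(swapped), model)
        assert abs(z) < np.arctanh(0.999999)  # clip engages only at |rho| = 1

    def test_label_mismatch_rejected(self):
        a = self._rdm([0.1, 0.5, 0.9], labels=["a", "b", "c"])
        b = self._rdm([0.1, 0.5, 0.9], labels=["a", "c", "b"])
        with pytest.raises(InvalidRDMError):
            correlate_rdms(a, b)

    def test_constant_vector_undefined(self):
        a = self._rdm([0.5, 0.5, 0.5])
        b = self._rdm([0.1, 0.2, 0.3])
        assert np.isnan(correlate_rdms(a, b))


@pytest.fixture(scope="module")
def planted(tiny_anatomy):
    """Logo-grapheme structure planted in the left middle fusiform."""
    seed = 9
    stimuli, emb = syn.generate_stimulus_set(seed)
    plants = syn.PlantConfig(
        plants=[syn.RegionPlant(syn.LABELS["L_mid_FG"], "logo_grapheme", ("RW",), 3.0)]
    )
    tb = syn.simulate_trial_betas(seed, 0, tiny_anatomy, stimuli, emb, plants,
                                  beta_noise_sd=0.5)
    from votrsa.stimuli import build_logo_grapheme_rdm

    model = build_logo_grapheme_rdm(stimuli.for_condition("RW"))
    return tiny_anatomy, tb["RW"], model


class TestSearchlightMap:
    def test_equals_brute_force_per_voxel_computation(self, planted):
        anatomy, series, model = planted
        roi = anatomy.mask(syn.ROI_LABELS)
        spec = SearchlightSpec(min_voxels=5)
        m = searchlight_representation_map(series, model, spec, roi)
        vs = np.linalg.norm(series.affine[:3, :3], axis=0)
        offs = sphere_offsets(spec.radius_mm, vs)
        for center in map(tuple, np.argwhere(roi)[::17]):
            rdm = neural_rdm_at(center, series, spec, roi, offs)
            expect = correlate_rdms(rdm, model, spec.rho_clip)
            assert m.z[center] == pytest.approx(expect, abs=0, rel=0) or (
                np.isnan(m.z[center]) and np.isnan(expect)
            )

    def test_planted_region_carries_highest_z(self, planted):
        anatomy, series, model = planted
        roi = anatomy.mask(syn.ROI_LABELS)
        m = searchlight_representation_map(series, model, SearchlightSpec(min_voxels=5), roi)
        plant_mean = np.nanmean(m.z[anatomy.mask(syn.LABELS["L_mid_FG"])])
        other = roi & ~anatomy.mask(syn.LABELS["L_mid_FG"])
        assert plant_mean > np.nanmean(m.z[other]) + 0.2
        argmax = np.unravel_index(np.nanargmax(np.nan_to_num(m.z, nan=-np.inf)), m.z.shape)
        assert anatomy.data[argmax] == syn.LABELS["L_mid_FG"]

    def test_pure_noise_map_centers_on_zero(self, tiny_anatomy):
        stimuli, emb = syn.generate_stimulus_set(9)
        tb = syn.simulate_trial_betas(31, 0, tiny_anatomy, stimuli, emb,
                                      syn.null_plant_config(), beta_noise_sd=0.5)
        from votrsa.stimuli import build_logo_grapheme_rdm

        model = build_logo_grapheme_rdm(stimuli.for_condition("RW"))
        roi = tiny_anatomy.mask(syn.ROI_LABELS)
        m = searchlight_representation_map(tb["RW"], model, SearchlightSpec(min_voxels=5), roi)
        vals = m.z[np.isfinite(m.z)]
        assert abs(vals.mean()) < 2 * vals.std() / np.sqrt(max(len(vals) / 60, 1))

    def test_consistent_trial_relabeling_leaves_map_unchanged(self, planted, rng):
        anatomy, series, model = planted
        roi = anatomy.mask(syn.ROI_LABELS)
        spec = SearchlightSpec(min_voxels=5)
        base = searchlight_representation_map(series, model, spec, roi)
        perm = rng.permutation(series.n_trials)
        series_p = TrialBetaSeries(
            series.data[..., perm], [series.stim_ids[i] for i in perm],
            series.condition, series.affine,
        )
        model_p = RDM(
            [model.labels[i] for i in perm],
            model.values[np.ix_(perm, perm)], model.kind,
        )
        shuffled = searchlight_representation_map(series_p, model_p, spec, roi)
        assert np.allclose(base.z, shuffled.z, equal_nan=True)

    def test_error_trial_exclusion_keeps_pair_alignment(self, planted):
        """Dropping trials shrinks neural and model RDMs identically."""
        anatomy, series, model = planted
        keep = series.stim_ids[::2]
        sub_series = series.subset(keep)
        sub_model = model.subset(keep)
        assert sub_series.stim_ids == sub_model.labels
        n = len(keep)
        assert sub_model.values.shape == (n, n)
        roi = anatomy.mask(syn.ROI_LABELS)
        m = searchlight_representation_map(
            sub_series, sub_model, SearchlightSpec(min_voxels=5), roi
        )
        assert np.isfinite(m.z[anatomy.mask(syn.LABELS["L_mid_FG"])]).all()

    def test_empty_roi_rejected(self, planted):
        _, series, model = planted
        with pytest.raises(ConfigurationError):
            searchlight_representation_map(
                series, model, SearchlightSpec(), np.zeros(series.data.shape[:3], bool)
            )


class TestGroupRSA:
    def _maps(self, rng, n_sub, shape=(8, 8, 8), plant=None):
        maps = []
        for _ in range(n_sub):
            z = rng.normal(0, 0.1, size=shape)
            if plant is not None:
                z[plant] += 0.5
            maps.append(RepresentationMap(z, np.zeros(shape), np.eye(4), "logo_grapheme", "RW"))
        return maps

    def test_planted_region_recovered(self, rng):
        shape = (8, 8, 8)
        plant = np.zeros(shape, bool)
        plant[2:6, 2:6, 2:6] = True
        maps = self._maps(rng, 12, shape, plant)
        t, p, clusters = group_rsa_inference(maps, np.ones(shape, bool))
        assert len(clusters) >= 1
        best = max(
            dice_overlap(clusters.cluster_mask(c), plant) for c in clusters.frame.cluster_id
        )
        assert best > 0.5

    def test_negated_maps_produce_no_survivors(self, rng):
        shape = (8, 8, 8)
        plant = np.zeros(shape, bool)
        plant[2:6, 2:6, 2:6] = True
        maps = self._maps(rng, 12, shape, plant)
        neg = [
            RepresentationMap(-m.z, m.sphere_size, m.affine, m.model_kind, m.condition)
            for m in maps
        ]
        _, _, clusters = group_rsa_inference(neg, np.ones(shape, bool))
        assert len(clusters) == 0


class TestClusterMeansAndCrossRegion:
    def test_cluster_mean_constant_and_single_voxel(self):
        shape = (4, 4, 4)
        m1 = RepresentationMap(np.full(shape, 0.7), np.zeros(shape), np.eye(4), "semantic", "RW")
        mask = np.zeros(shape, bool)
        mask[1, 2, 3] = True
        assert cluster_mean_representation([m1], mask)[0] == pytest.approx(0.7)
        m1.z[1, 2, 3] = -0.2
        assert cluster_mean_representation([m1], mask)[0] == pytest.approx(-0.2)
        with pytest.raises(ConfigurationError):
            cluster_mean_representation([m1], np.zeros(shape, bool))

    def test_cluster_mean_matches_direct_average(self, rng):
        shape = (5, 5, 5)
        mask = rng.random(shape) < 0.3
        maps = [
            RepresentationMap(rng.normal(size=shape), np.zeros(shape), np.eye(4), "semantic", "RW")
            for _ in range(4)
        ]
        got = cluster_mean_representation(maps, mask)
        assert np.allclose(got, [m.z[mask].mean() for m in maps])

    def test_identity_and_reversal(self):
        a = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        rho, _ = cross_region_correlation(a, a)
        assert rho == pytest.approx(1.0)
        rho, _ = cross_region_correlation(a, -a)
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_p_matches_exhaustive_oracle(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        rho, p = cross_region_correlation(a, b)
        # oracle: all 720 permutations through an independent spearman
        count = 0
        for perm in itertools.permutations(range(6)):
            r = stats.spearmanr(a, b[list(perm)]).statistic
            count += abs(r) >= abs(rho) - 1e-12
        assert p == pytest.approx(count / 720)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            cross_region_correlation(np.ones(6), np.arange(6.0))
        with pytest.raises(ConfigurationError):
            cross_region_correlation(np.arange(3.0), np.arange(3.0))
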