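"""Group inference, FDR, clusters, gradients, behavior and exclusions."""

import numpy as np
import pandas as pd
import pytest

from votrsa import (
    apply_exclusions,
    behavioral_stats,
    extract_clusters,
    fdr_threshold,
    gradient_profile,
    group_onesample_t,
)
from votrsa.errors import ConfigurationError, DegenerateConditionError, IncompleteDesignError


def _vol(values):
    """Pack a 1D p/stat vector into a (n,1,1) volume with a full mask."""
    arr = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return arr, np.ones(arr.shape, dtype=bool)


class TestGroupT:
    def test_hand_computed_example(self):
        maps = [np.full((2, 2, 2), v) for v in (0.2, 0.1, 0.3, 0.2)]
        mask = np.ones((2, 2, 2), dtype=bool)
        t, p, df = group_onesample_t(maps, mask, tail="two")
        assert df == 3
        assert t[0, 0, 0] == pytest.approx(0.2 / (np.std([0.2, 0.1, 0.3, 0.2], ddof=1) / 2), abs=1e-9)
        assert t[0, 0, 0] == pytest.approx(4.898979, abs=1e-5)

    def test_zero_variance_flagged_nan(self):
        maps = [np.zeros((2, 2, 2))] * 4
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.warns(UserWarning, match="undefined t"):
            t, p, _ = group_onesample_t(maps, mask)
        assert np.isnan(t[mask]).all()

    def test_sign_flip_antisymmetry(self, rng):
        maps = [rng.normal(size=(3, 3, 3)) for _ in range(6)]
        mask = np.ones((3, 3, 3), dtype=bool)
        t_pos, p_pos, _ = group_onesample_t(maps, mask, tail="greater")
        t_neg, p_neg, _ = group_onesample_t([-m for m in maps], mask, tail="greater")
        assert np.allclose(t_pos, -t_neg)
        assert np.allclose(p_pos, 1.0 - p_neg)

    def test_fewer_than_three_subjects_rejected(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        with pytest.raises(ConfigurationError):
            group_onesample_t([np.zeros((2, 2, 2))] * 2, mask)


class TestFDR:
    def test_stepup_example_all_rejected(self):
        p, mask = _vol([0.01, 0.02, 0.03, 0.04])
        survivors, crit = fdr_threshold(p, mask, q=0.05)
        assert survivors.all()
        assert crit == pytest.approx(0.04)

    def test_all_ones_rejects_nothing(self):
        p, mask = _vol([1.0] * 8)
        survivors, crit = fdr_threshold(p, mask, q=0.05)
        assert not survivors.any()
        assert crit == 0.0

    def test_matches_independent_stepup_oracles(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(300):
            m = int(rng.integers(1, 60))
            pv = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            p, mask = _vol(pv)
            survivors, crit = fdr_threshold(p, mask, q=0.05)
            # oracle 1: manual step-up p(i) <= i q / m
            order = np.argsort(pv)
            sp = pv[order]
            passing = np.nonzero(sp <= 0.05 * np.arange(1, m + 1) / m)[0]
            expect = np.zeros(m, dtype=bool)
            if passing.size:
                expect[order[: passing[-1] + 1]] = True
            assert np.array_equal(survivors[:, 0, 0], expect)
            # oracle 2: statsmodels BH
            reject_sm = multipletests(pv, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(survivors[:, 0, 0], reject_sm)

    def test_empty_mask_rejected(self):
        with pytest.raises(ConfigurationError):
            fdr_threshold(np.zeros((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool), 0.05)


from cluster_oracle import flood_fill_components as _flood_fill_components  # noqa: E402


class TestClusters:
    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for trial in range(8):
            mask = rng.random((12, 12, 12)) < 0.25
            stat = rng.normal(size=mask.shape)
            for conn in (6, 18, 26):
                ct = extract_clusters(mask, stat, np.eye(4), min_size=3, connectivity=conn)
                oracle = {c for c in _flood_fill_components(mask, conn) if len(c) > 3}
                got = {
                    frozenset(map(tuple, np.argwhere(ct.label_volume == cid)))
                    for cid in ct.frame.cluster_id
                }
                assert got == oracle

    def test_strict_size_rule_and_sizes(self):
        mask = np.zeros((20, 8, 8), dtype=bool)
        mask[0:12, 0, 0] = True   # size 12 line
        mask[0:5, 4, 4] = True    # size 5 line
        stat = np.ones(mask.shape)
        ct = extract_clusters(mask, stat, np.eye(4), min_size=10)
        assert len(ct) == 1 and ct.frame.iloc[0]["size"] == 12

    def test_component_of_exactly_min_size_dropped(self):
        mask = np.zeros((12, 4, 4), dtype=bool)
        mask[0:10, 1, 1] = True  # exactly 10 voxels
        ct = extract_clusters(mask, np.ones(mask.shape), np.eye(4), min_size=10)
        assert len(ct) == 0

    def test_empty_mask_gives_empty_table(self):
        ct = extract_clusters(np.zeros((4, 4, 4), dtype=bool), np.zeros((4, 4, 4)), np.eye(4))
        assert len(ct) == 0

    def test_peak_is_in_cluster_and_in_mm(self):
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[1:5, 2, 2] = True
        stat = np.zeros(mask.shape)
        stat[3, 2, 2] = 7.5
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = -5.0
        ct = extract_clusters(mask, stat, affine, min_size=2)
        row = ct.frame.iloc[0]
        assert row.peak_stat == 7.5
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (1.0, -1.0, -1.0)


class TestGradientProfile:
    def test_constant_map_flat(self):
        vol = np.full((6, 12, 6), 3.5)
        roi = np.ones_like(vol, dtype=bool)
        prof = gradient_profile(vol, roi, np.eye(4), n_bins=4)
        assert np.allclose(prof["mean"], 3.5)

    def test_y_coordinate_map_strictly_increasing(self):
        shape = (4, 20, 4)
        vol = np.tile(np.arange(20.0)[None, :, None], (4, 1, 4))
        prof = gradient_profile(vol, np.ones(shape, bool), np.eye(4), n_bins=5)
        assert (np.diff(prof["mean"]) > 0).all()
        assert (np.diff(prof["bin_center_mm"]) > 0).all()  # posterior -> anterior

    def test_planted_anterior_effect_peaks_in_most_anterior_bin(self, rng):
        shape = (5, 18, 5)
        vol = rng.normal(0, 0.01, size=shape)
        vol[:, 15:, :] += 5.0
        prof = gradient_profile(vol, np.ones(shape, bool), np.eye(4), n_bins=6)
        # oracle: direct per-bin averaging
        assert prof["mean"].idxmax() == len(prof) - 1

    def test_sparse_roi_warns(self):
        roi = np.zeros((4, 10, 4), dtype=bool)
        roi[2, 0, 2] = True
        with pytest.warns(UserWarning, match="bins occupied"):
            gradient_profile(np.ones(roi.shape), roi, np.eye(4), n_bins=5)


def _behavior_table(rng, n=12):
    rows = []
    effects = {"RW": 0.95, "PW": 0.80, "FW": 0.96, "SC": 0.98}
    rts = {"RW": 790.0, "PW": 940.0, "FW": 780.0, "SC": 730.0}
    for s in range(n):
        subj_shift = rng.normal(0, 0.02)
        for c, acc in effects.items():
            rows.append(
                {"subject": f"s{s}", "condition": c,
                 "acc": np.clip(acc + subj_shift + rng.normal(0, 0.03), 0, 1),
                 "rt": rts[c] + rng.normal(0, 40)}
            )
    return pd.DataFrame(rows)


class TestBehavior:
    def test_dfs_for_51_subjects(self, rng):
        tbl = _behavior_table(rng, n=51)
        res = behavioral_stats(tbl)
        assert (res["acc"]["df1"], res["acc"]["df2"]) == (3, 150)
        assert (res["rt"]["df1"], res["rt"]["df2"]) == (3, 150)
        assert len(res["acc"]["pairwise"]) == 6
        assert (res["acc"]["pairwise"].p_bonferroni <= 1.0).all()

    def test_matches_sums_of_squares_oracle(self, rng):
        tbl = _behavior_table(rng, n=6)
        res = behavioral_stats(tbl)
        wide = tbl.pivot(index="subject", columns="condition", values="acc").to_numpy()
        n, k = wide.shape
        grand = wide.mean()
        ss_cond = n * ((wide.mean(axis=0) - grand) ** 2).sum()
        resid = wide - wide.mean(axis=1, keepdims=True) - wide.mean(axis=0) + grand
        ss_err = (resid**2).sum()
        f_expect = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        assert res["acc"]["F"] == pytest.approx(f_expect, rel=1e-8)

    def test_invariant_to_per_subject_constant(self, rng):
        tbl = _behavior_table(rng, n=8)
        res1 = behavioral_stats(tbl)
        shifted = tbl.copy()
        offsets = {f"s{i}": 50.0 * i for i in range(8)}
        shifted["rt"] = shifted.rt + shifted.subject.map(offsets)
        res2 = behavioral_stats(shifted)
        assert res1["rt"]["F"] == pytest.approx(res2["rt"]["F"], rel=1e-9)

    def test_incomplete_design_rejected(self, rng):
        tbl = _behavior_table(rng, n=5).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            behavioral_stats(tbl)


def _subject_events(acc_by_cond, n=8):
    rows = []
    onset = 4.0
    for c, acc_frac in acc_by_cond.items():
        n_correct = int(round(acc_frac * n))
        for i in range(n):
            rows.append(
                {"onset": onset, "duration": 0.6, "trial_type": c,
                 "stim_id": f"{c}{i:02d}", "accuracy": int(i < n_correct), "rt": 800.0}
            )
            onset += 5.0
    return pd.DataFrame(rows)


class TestExclusions:
    def test_all_correct_subject_unchanged(self):
        ev = {"s1": _subject_events({c: 1.0 for c in ("RW", "PW", "FW", "SC")})}
        kept, report = apply_exclusions(ev)
        assert report["excluded_subjects"] == []
        assert len(kept["s1"]) == 32

    def test_low_pw_accuracy_subject_dropped(self):
        ev = {
            "good": _subject_events({"RW": 1.0, "PW": 0.75, "FW": 1.0, "SC": 1.0}),
            "bad": _subject_events({"RW": 1.0, "PW": 0.375, "FW": 1.0, "SC": 1.0}),
        }
        kept, report = apply_exclusions(ev)
        assert report["excluded_subjects"] == ["bad"]
        assert set(kept) == {"good"}

    def test_counts_match_direct_filter(self, rng):
        ev = {}
        for s in range(6):
            accs = {c: float(rng.choice([0.625, 0.75, 1.0])) for c in ("RW", "PW", "FW", "SC")}
            ev[f"s{s}"] = _subject_events(accs)
        kept, report = apply_exclusions(ev)
        for name, f in ev.items():
            if f.loc[f.trial_type == "PW", "accuracy"].mean() < 0.5:
                assert name in report["excluded_subjects"]
            else:
                assert len(kept[name]) == int(f.accuracy.sum())

    def test_degenerate_condition_raises(self):
        ev = {"s1": _subject_events({"RW": 1.0, "PW": 0.5, "FW": 0.0, "SC": 1.0})}
        with pytest.raises(DegenerateConditionError):
            apply_exclusions(ev)
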