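"""Spatial correlation, GEV, AAHC, grand means and template sorting."""

import itertools

import numpy as np
import pytest

import microstates as ms
from microstates.clustering import TemplateSet, aahc

from oracles import best_partition_gev, gev_direct


def _random_maps(rng, n, e=25):
    X = rng.normal(size=(n, e))
    X -= X.mean(axis=1, keepdims=True)
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def _orthogonal_templates(rng, k, e):
    A = rng.normal(size=(e, k))
    A -= A.mean(axis=0, keepdims=True)  # average-referenced span
    Q, _ = np.linalg.qr(A)
    return TemplateSet(maps=Q.T, labels=tuple("ABCDEF"[:k]))


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self, rng):
        u = rng.normal(size=25)
        assert ms.spatial_correlation(u, u) == pytest.approx(1.0)

    def test_negation_with_polarity_invariance(self, rng):
        u = rng.normal(size=25)
        assert ms.spatial_correlation(u, -u, polarity_invariant=True) == pytest.approx(1.0)
        assert ms.spatial_correlation(u, -u, polarity_invariant=False) == pytest.approx(-1.0)

    def test_orthogonal_maps(self):
        u = np.array([1.0, -1, 1, -1])
        v = np.array([1.0, 1, -1, -1])
        assert ms.spatial_correlation(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ms.spatial_correlation(np.ones(5), np.arange(5.0))


class TestGEV:
    def test_perfect_assignment_gives_one(self, rng):
        ts = _orthogonal_templates(rng, 3, 10)
        scales = rng.uniform(0.5, 2.0, size=9)
        assignment = np.repeat(np.arange(3), 3)
        maps = ts.maps[assignment] * scales[:, None]
        w = rng.uniform(1, 3, size=9)
        per_class, total = ms.gev(maps, w, ts, assignment)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_assignment_gives_zero(self, rng):
        ts = _orthogonal_templates(rng, 2, 10)
        # maps equal to template 1, assigned to orthogonal template 0
        maps = np.tile(ts.maps[1], (4, 1))
        per_class, total = ms.gev(maps, np.ones(4), ts, np.zeros(4, dtype=int))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            ts = _orthogonal_templates(rng, 3, 12)
            maps = rng.normal(size=(10, 12))
            w = rng.uniform(0.5, 3.0, size=10)
            a = rng.integers(0, 3, size=10)
            got_pc, got_total = ms.gev(maps, w, ts, a)
            exp_pc, exp_total = gev_direct(maps, w, ts.maps, a)
            np.testing.assert_allclose(got_pc, exp_pc, atol=1e-12)
            assert got_total == pytest.approx(exp_total, abs=1e-12)

    def test_unassigned_maps_count_in_denominator_only(self, rng):
        ts = _orthogonal_templates(rng, 2, 8)
        maps = np.vstack([ts.maps[0], ts.maps[1]])
        w = np.array([1.0, 1.0])
        _, total = ms.gev(maps, w, ts, np.array([0, -1]))
        assert total == pytest.approx(0.5, abs=1e-12)

    def test_all_zero_gfp_rejected(self, rng):
        ts = _orthogonal_templates(rng, 2, 8)
        with pytest.raises(ValueError, match="GFP"):
            ms.gev(ts.maps, np.zeros(2), ts, np.array([0, 1]))


class TestAAHC:
    def test_duplicate_pairs_recovered_exactly(self, rng):
        truth = _orthogonal_templates(rng, 3, 10)
        maps = np.vstack([truth.maps, -truth.maps])  # sign-flipped duplicates
        ts, assignment = aahc(maps, np.ones(6), 3)
        assert ts.gev == pytest.approx(1.0, abs=1e-9)
        C = np.abs(ts.maps @ truth.maps.T)
        # each recovered template matches exactly one original
        assert np.allclose(np.sort(C.max(axis=1)), 1.0, atol=1e-9)
        assert set(C.argmax(axis=1)) == {0, 1, 2}
        # the two copies of each map land in the same cluster
        assert all(assignment[i] == assignment[i + 3] for i in range(3))

    def test_k_equals_map_count_explains_everything(self, rng):
        maps = _random_maps(rng, 5, 10)
        ts, _ = aahc(maps, np.ones(5), 5)
        assert ts.gev == pytest.approx(1.0, abs=1e-9)

    def test_gev_non_increasing_in_k(self, rng):
        maps = _random_maps(rng, 30, 12)
        w = rng.uniform(0.5, 2.0, size=30)
        gevs = [aahc(maps, w, k)[0].gev for k in (8, 6, 4, 3, 2)]
        for hi, lo in zip(gevs[:-1], gevs[1:]):
            assert lo <= hi + 1e-9

    def test_polarity_invariance_under_random_sign_flips(self, rng):
        maps = _random_maps(rng, 20, 10)
        w = rng.uniform(0.5, 2.0, size=20)
        ts1, a1 = aahc(maps, w, 4)
        flips = rng.choice([-1.0, 1.0], size=20)
        ts2, a2 = aahc(maps * flips[:, None], w, 4)
        assert ts1.gev == pytest.approx(ts2.gev, abs=1e-9)
        np.testing.assert_array_equal(a1, a2)
        C = np.abs(ts1.maps @ ts2.maps.T)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-9)

    def test_near_optimal_vs_exhaustive_partition_oracle(self, rng):
        """12 noisy maps from 3 templates: AAHC reaches >= 95% of the optimum."""
        truth = _orthogonal_templates(rng, 3, 8)
        assignment = np.repeat(np.arange(3), 4)
        maps = truth.maps[assignment] + 0.2 * rng.normal(size=(12, 8))
        w = rng.uniform(1.0, 2.0, size=12)
        ts, _ = aahc(maps, w, 3)
        optimum = best_partition_gev(maps, w, 3)
        assert ts.gev >= 0.95 * optimum

    def test_invalid_k_rejected(self, rng):
        maps = _random_maps(rng, 5, 8)
        for bad in (0, 6):
            with pytest.raises(ValueError):
                aahc(maps, np.ones(5), bad)


class TestFitIndividual:
    def test_noiseless_subject_recovers_templates(self):
        cfg = ms.SimulationConfig(snr=np.inf, n_epochs=2, epoch_s=10.0)
        truth = ms.sample_label_sequence(cfg, seed=1)
        rec = ms.synthesize_recording(truth, seed=2)
        gfp = ms.detect_gfp_peaks(ms.compute_gfp(rec), rec.epochs)
        ts = ms.fit_individual_microstates(rec, gfp)
        st = ms.sort_templates(ts, cfg.templates)
        for k in range(4):
            assert ms.spatial_correlation(st.maps[k], cfg.templates.maps[k]) >= 0.999

    def test_noisy_subject_recovers_templates(self, short_config):
        truth = ms.sample_label_sequence(short_config, seed=3)
        rec = ms.synthesize_recording(truth, seed=4)  # snr = 2
        gfp = ms.detect_gfp_peaks(ms.compute_gfp(rec), rec.epochs)
        ts = ms.fit_individual_microstates(rec, gfp)
        st = ms.sort_templates(ts, short_config.templates)
        for k in range(4):
            assert ms.spatial_correlation(st.maps[k], short_config.templates.maps[k]) >= 0.95

    def test_fitted_beats_random_orthogonal_templates(self, short_config, rng):
        truth = ms.sample_label_sequence(short_config, seed=5)
        rec = ms.synthesize_recording(truth, seed=6)
        gfp = ms.detect_gfp_peaks(ms.compute_gfp(rec), rec.epochs)
        fitted = ms.fit_individual_microstates(rec, gfp)
        random_ts = _orthogonal_templates(rng, 4, rec.n_channels)
        seg_r = ms.backfit(rec, gfp, random_ts)
        _, gev_random = ms.assignment_quality(seg_r, rec, gfp, random_ts)
        assert fitted.gev > gev_random

    def test_too_few_peaks_rejected(self, montage, rng):
        rec = ms.EEGRecording(
            data=rng.normal(size=(25, 100)), fs_hz=250.0, montage=montage
        )
        gfp = ms.GFPSeries(values=np.zeros(100), peak_indices=np.array([5, 9]))
        with pytest.raises(ValueError, match="peaks"):
            ms.fit_individual_microstates(rec, gfp, 4)


class TestSortTemplates:
    def test_identity(self, canonical):
        out = ms.sort_templates(canonical, canonical)
        np.testing.assert_allclose(out.maps, canonical.maps, atol=1e-12)

    def test_recovers_shuffle_and_sign_flips(self, canonical, rng):
        perm = rng.permutation(4)
        flips = rng.choice([-1.0, 1.0], size=4)
        shuffled = TemplateSet(
            maps=canonical.maps[perm] * flips[:, None], labels=("w", "x", "y", "z")
        )
        out = ms.sort_templates(shuffled, canonical)
        np.testing.assert_allclose(out.maps, canonical.maps, atol=1e-12)
        assert out.labels == canonical.labels

    def test_objective_matches_independent_exhaustive_search(self, rng):
        a = TemplateSet(maps=_random_maps(rng, 4, 10))
        b = TemplateSet(maps=_random_maps(rng, 4, 10))
        out = ms.sort_templates(a, b)
        achieved = sum(
            abs(float(out.maps[j] @ b.maps[j])) for j in range(4)
        )
        best = max(
            sum(abs(float(a.maps[p[j]] @ b.maps[j])) for j in range(4))
            for p in itertools.permutations(range(4))
        )
        assert achieved == pytest.approx(best, abs=1e-12)

    def test_mismatched_k_rejected(self, canonical, rng):
        with pytest.raises(ValueError):
            ms.sort_templates(TemplateSet(maps=_random_maps(rng, 3, 25), labels=("a", "b", "c")), canonical)


class TestGrandMean:
    def test_identical_sets_average_to_themselves(self, canonical):
        out = ms.grand_mean([canonical, canonical, canonical])
        np.testing.assert_allclose(out.maps, canonical.maps, atol=1e-12)

    def test_permuted_flipped_sets_align_before_averaging(self, canonical, rng):
        perm = rng.permutation(4)
        flips = rng.choice([-1.0, 1.0], size=4)
        other = TemplateSet(maps=canonical.maps[perm] * flips[:, None])
        out = ms.grand_mean([canonical, other])
        C = np.abs(out.maps @ canonical.maps.T)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)

    def test_mean_is_most_central(self, rng):
        """The aligned mean correlates with the inputs at least as well on
        average as any single input does."""
        base = _random_maps(rng, 4, 15)
        sets = [
            TemplateSet(maps=base + 0.15 * rng.normal(size=base.shape))
            for _ in range(5)
        ]
        gm = ms.grand_mean(sets)
        aligned = [ms.sort_templates(s, gm) for s in sets]

        def mean_corr(ref):
            return np.mean(
                [np.mean(np.abs(np.sum(ref.maps * s.maps, axis=1))) for s in aligned]
            )

        gm_score = mean_corr(gm)
        for s in aligned:
            assert gm_score >= mean_corr(s) - 1e-9

    def test_incompatible_k_rejected(self, canonical, rng):
        bad = TemplateSet(maps=_random_maps(rng, 3, 25), labels=("a", "b", "c"))
        with pytest.raises(ValueError):
            ms.grand_mean([canonical, bad])
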