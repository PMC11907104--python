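"""Synthetic cohort generator: templates, dynamics, projection, cohorts."""

import numpy as np
import pytest

import microstates as ms
from microstates.montage import Montage
from microstates.synthetic import uniform_transitions


class TestCanonicalTemplates:
    def test_maps_are_average_referenced_and_unit_norm(self, canonical):
        assert canonical.k == 4
        np.testing.assert_allclose(canonical.maps.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(canonical.maps, axis=1), 1, atol=1e-12)

    def test_maps_are_distinct(self, canonical):
        for i in range(4):
            for j in range(i + 1, 4):
                assert ms.spatial_correlation(canonical.maps[i], canonical.maps[j]) < 0.999

    def test_polarity_invariant_self_correlation(self, canonical):
        for m in canonical.maps:
            assert ms.spatial_correlation(m, -m) == pytest.approx(1.0)

    def test_expected_axis_orientations(self, canonical, montage):
        """A and B load on the two diagonals, C front-back, D centre-periphery."""
        pos = montage.position_array()
        x, y = pos[:, 0], pos[:, 1]
        a, b, c, d = canonical.maps
        assert ms.spatial_correlation(a, x + y) == pytest.approx(1.0)
        assert ms.spatial_correlation(b, y - x) == pytest.approx(1.0)
        assert ms.spatial_correlation(c, y) == pytest.approx(1.0)
        # D: central electrodes above the periphery (monotone in radius)
        r = np.sqrt(x**2 + (y - 0.15) ** 2)
        assert np.corrcoef(d, -r)[0, 1] > 0.9

    def test_missing_position_raises_with_electrode_name(self):
        m = Montage(labels=("Cz", "Pz"), positions={"Cz": (0.0, 0.0)})
        with pytest.raises(ValueError, match="Pz"):
            ms.make_canonical_templates(m)

    def test_canonical_set_is_exactly_four(self, montage):
        with pytest.raises(ValueError):
            ms.make_canonical_templates(montage, k=5)


class TestLabelSequence:
    def test_forced_alternation_with_fixed_dwell(self):
        """A<->B chain with a near-degenerate 80 ms dwell gives 20-sample blocks."""
        P = np.zeros((4, 4))
        P[0, 1] = P[1, 0] = 1.0
        P[2, 3] = P[3, 2] = 1.0
        cfg = ms.SimulationConfig(
            transition_matrix=P, dwell_mean_ms=80.0, dwell_shape=1e7,
            n_epochs=1, epoch_s=1.0,
        )
        truth = ms.sample_label_sequence(cfg, seed=0)
        labels = truth.label_sequence
        first = labels[0]
        blocks = labels[:240].reshape(-1, 20)  # last segment is epoch-truncated
        assert (blocks == blocks[:, :1]).all()  # constant within blocks
        assert (np.diff(blocks[:, 0]) != 0).all()  # alternating between blocks
        assert set(blocks[:, 0]) <= {first, 1 - first} or set(blocks[:, 0]) <= {2, 3}

    def test_segments_tile_each_epoch(self, short_config):
        truth = ms.sample_label_sequence(short_config, seed=1)
        n = short_config.samples_per_epoch
        for e in range(short_config.n_epochs):
            segs = [s for s in truth.segment_list if n * e <= s[0] < n * (e + 1)]
            assert segs[0][0] == n * e
            assert segs[-1][1] == n * (e + 1)
            for (a, b, _), (c, d, _) in zip(segs[:-1], segs[1:]):
                assert b == c

    def test_empirical_dwell_mean_within_5pct(self):
        cfg = ms.SimulationConfig(dwell_mean_ms=80.0, n_epochs=10, epoch_s=20.0)
        truth = ms.sample_label_sequence(cfg, seed=7)
        # exclude epoch-truncated final segments whose dwell was cut short
        bounds = {b for _, b in truth.epoch_bounds()}
        starts = {a for a, _ in truth.epoch_bounds()}
        full = [
            (b - a) for a, b, _ in truth.segment_list
            if b not in bounds and a not in starts
        ]
        mean_ms = np.mean(full) / cfg.fs_hz * 1000
        assert mean_ms == pytest.approx(80.0, rel=0.05)

    def test_empirical_transition_frequencies_match_matrix(self):
        P = np.array(
            [[0.0, 0.6, 0.2, 0.2],
             [0.5, 0.0, 0.3, 0.2],
             [0.1, 0.3, 0.0, 0.6],
             [0.4, 0.3, 0.3, 0.0]]
        )
        cfg = ms.SimulationConfig(transition_matrix=P, n_epochs=10, epoch_s=20.0)
        truth = ms.sample_label_sequence(cfg, seed=11)
        counts = np.zeros((4, 4))
        for (a, b, ci), (c, d, cj) in zip(truth.segment_list[:-1], truth.segment_list[1:]):
            if b == c:  # same epoch
                counts[ci, cj] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(freq, P, atol=0.05)

    def test_zero_row_transition_matrix_rejected(self):
        P = uniform_transitions(4)
        P[2] = 0.0
        with pytest.raises(ValueError, match="zero|sum"):
            ms.SimulationConfig(transition_matrix=P)

    def test_bit_exact_reproducibility(self, short_config):
        t1 = ms.sample_label_sequence(short_config, seed=5)
        t2 = ms.sample_label_sequence(short_config, seed=5)
        np.testing.assert_array_equal(t1.label_sequence, t2.label_sequence)
        assert t1.segment_list == t2.segment_list


class TestSynthesizeRecording:
    @pytest.fixture()
    def noiseless(self, short_config):
        cfg = ms.SimulationConfig(
            snr=np.inf, n_epochs=short_config.n_epochs, epoch_s=short_config.epoch_s
        )
        truth = ms.sample_label_sequence(cfg, seed=2)
        return truth, ms.synthesize_recording(truth, seed=3)

    def test_noiseless_peak_maps_match_active_template(self, noiseless):
        truth, rec = noiseless
        gfp = ms.detect_gfp_peaks(ms.compute_gfp(rec), rec.epochs)
        tmpl = truth.config.templates.maps
        for t in gfp.peak_indices[:200]:
            corr = ms.spatial_correlation(rec.data[:, t], tmpl[truth.label_sequence[t]])
            assert corr >= 0.999

    def test_output_is_average_referenced(self, short_config):
        truth = ms.sample_label_sequence(short_config, seed=2)
        rec = ms.synthesize_recording(truth, seed=3)
        scale = np.abs(rec.data).max()
        assert np.abs(rec.data.mean(axis=0)).max() < 1e-9 * scale

    def test_doubling_amplitude_doubles_gfp(self, short_config):
        from dataclasses import replace

        cfg1 = ms.SimulationConfig(snr=np.inf, n_epochs=1, epoch_s=5.0)
        truth1 = ms.sample_label_sequence(cfg1, seed=4)
        cfg2 = replace(cfg1, amplitude_uv=cfg1.amplitude_uv * 2)
        truth2 = ms.GroundTruth(truth1.label_sequence, truth1.segment_list, cfg2)
        r1 = ms.synthesize_recording(truth1, seed=9)
        r2 = ms.synthesize_recording(truth2, seed=9)
        g1 = ms.detect_gfp_peaks(ms.compute_gfp(r1), r1.epochs)
        g2 = ms.detect_gfp_peaks(ms.compute_gfp(r2), r2.epochs)
        m1 = g1.values[g1.peak_indices].mean()
        m2 = g2.values[g2.peak_indices].mean()
        assert m2 == pytest.approx(2 * m1, rel=1e-9)

    def test_configured_snr_is_realized(self, short_config):
        truth = ms.sample_label_sequence(short_config, seed=6)
        noisy = ms.synthesize_recording(truth, seed=7)
        from dataclasses import replace

        clean_cfg = replace(short_config, snr=np.inf)
        clean = ms.synthesize_recording(
            ms.GroundTruth(truth.label_sequence, truth.segment_list, clean_cfg), seed=7
        )
        signal_rms = np.sqrt(np.mean(clean.data**2))
        noise_rms = np.sqrt(np.mean((noisy.data - clean.data) ** 2))
        assert signal_rms / noise_rms == pytest.approx(short_config.snr, rel=0.05)


class TestMakeCohort:
    def test_same_seed_gives_identical_cohorts(self, short_config):
        r1 = ms.make_cohort(2, short_config, seed=42)
        r2 = ms.make_cohort(2, short_config, seed=42)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.data, b.data)
            assert a.subject_id == b.subject_id and a.group == b.group

    def test_null_effect_groups_share_distribution(self, short_config):
        """Identity effect: group configs are equal, only subject RNG differs."""
        eff = ms.GroupEffect()
        cfg2 = eff.apply(short_config)
        np.testing.assert_array_equal(cfg2.transition_matrix, short_config.transition_matrix)
        np.testing.assert_array_equal(cfg2.dwell_mean_ms, short_config.dwell_mean_ms)
        np.testing.assert_array_equal(cfg2.amplitude_uv, short_config.amplitude_uv)

    def test_negative_probability_effect_rejected(self, short_config):
        delta = np.zeros((4, 4))
        delta[0, 1] = -0.5  # base off-diagonal is 1/3
        eff = ms.GroupEffect(transition_delta=delta)
        with pytest.raises(ValueError, match="negative"):
            eff.apply(short_config)

    def test_migraine_flag_covers_two_thirds(self, short_config):
        recs = ms.make_cohort(3, short_config, seed=0)
        for grp in ("control", "vss"):
            flags = [r.migraine for r in recs if r.group == grp]
            assert sum(flags) == 2 and len(flags) == 3

    def test_dwell_multiplier_recovered_downstream(self):
        """A 0.85 dwell effect survives the fit-backfit-quantify chain."""
        cfg = ms.SimulationConfig(n_epochs=4, epoch_s=20.0)
        recs = ms.make_cohort(
            3, cfg, ms.GroupEffect(dwell_scale=0.85), seed=17, jitter_sigma=0.02
        )
        means = {}
        for grp in ("control", "vss"):
            durs = []
            for rec in [r for r in recs if r.group == grp]:
                pre = ms.bandpass(ms.average_reference(rec))
                gfp = ms.detect_gfp_peaks(ms.compute_gfp(pre), pre.epochs)
                ts = ms.fit_individual_microstates(pre, gfp)
                seg = ms.backfit(pre, gfp, ts)
                table = ms.compute_parameters(seg, gfp)
                durs.append(table["duration_ms"].mean())
            means[grp] = np.mean(durs)
        assert means["vss"] / means["control"] == pytest.approx(0.85, abs=0.085)
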