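"""Generator tests: template geometry, semi-Markov dynamics, sensor model."""

import numpy as np
import pytest

from mstates import (
    ClinicalModel,
    CohortSpec,
    DynamicsSpec,
    Montage,
    hamd24_factor_scores,
    make_canonical_templates,
    simulate_cohort,
    simulate_state_sequence,
    spatial_correlation,
    synthesize_recording,
    temporal_parameters,
)

from conftest import rle_oracle

# scalp regions (unit disc, +y anterior, +x right) where each canonical
# class must place its extrema; the pair may be swapped by a sign flip
REGIONS = {
    "A": (lambda x, y: x > 0.2 and y > 0.2, lambda x, y: x < -0.2 and y < -0.2),
    "B": (lambda x, y: x < -0.2 and y > 0.2, lambda x, y: x > 0.2 and y < -0.2),
    "C": (lambda x, y: abs(x) < 0.3 and y > 0.3, lambda x, y: abs(x) < 0.3 and y < -0.3),
    "D": (lambda x, y: abs(x) < 0.35 and -0.15 < y < 0.65, lambda x, y: True),
}


class TestCanonicalTemplates:
    def test_orientations_sign_free(self, montage64, templates64):
        pos = montage64.positions
        for i, cls in enumerate(templates64.labels):
            m = templates64.maps[i]
            hi, lo = pos[np.argmax(m)], pos[np.argmin(m)]
            in_hi, in_lo = REGIONS[cls]
            direct = in_hi(*hi) and in_lo(*lo)
            flipped = in_hi(*lo) and in_lo(*hi)
            assert direct or flipped, f"class {cls}: extrema at {hi}, {lo}"

    def test_unit_norm_average_referenced(self, templates64):
        np.testing.assert_allclose(templates64.maps.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(templates64.maps, axis=1), 1, atol=1e-12)

    def test_deterministic(self, montage64):
        a = make_canonical_templates(montage64, seed=5, jitter=0.1)
        b = make_canonical_templates(montage64, seed=5, jitter=0.1)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_pairwise_correlations_below_07(self, templates64):
        k = templates64.k
        for i in range(k):
            for j in range(i + 1, k):
                r = spatial_correlation(templates64.maps[i], templates64.maps[j])
                assert r < 0.7, (i, j, r)

    def test_too_few_channels_rejected(self):
        m = Montage(("a", "b", "c"), np.array([[0.0, 0.5], [0.4, -0.3], [-0.4, -0.3]]))
        with pytest.raises(ValueError):
            make_canonical_templates(m)


class TestStateSequence:
    def test_forced_cycle_fixed_durations(self):
        # deterministic 80 ms dwell (infinite gamma shape), forced A<->B cycle
        tr = np.zeros((4, 4))
        tr[0, 1] = tr[1, 0] = 1.0
        tr[2, 3] = tr[3, 2] = 1.0  # rows for unvisited classes stay valid
        dyn = DynamicsSpec(
            mean_duration_ms=(80.0, 80.0, 80.0, 80.0),
            duration_shape=(np.inf,) * 4,
            transition=tr,
        )
        ls, gt = simulate_state_sequence(dyn, 10.0, 1000.0, seed=2)
        visited = sorted(set(ls.labels.tolist()))
        assert visited in ([0, 1], [2, 3])
        runs = rle_oracle(ls.labels)
        for cls, a, b in runs[:-1]:  # last run is truncated by the horizon
            assert b - a == 80
        a, b = visited
        assert gt.realized_transition.conditional[a, b] == 1.0
        assert gt.realized_transition.conditional[b, a] == 1.0

    def test_gamma_mean_duration_recovered(self):
        dyn = DynamicsSpec(mean_duration_ms=(60.0, 60.0, 80.0, 60.0))
        ls, gt = simulate_state_sequence(dyn, 300.0, 1000.0, seed=4)
        runs = rle_oracle(ls.labels)
        c_runs = [b - a for cls, a, b in runs if cls == 2]
        assert len(c_runs) > 1000
        assert abs(np.mean(c_runs) - 80.0) / 80.0 < 0.05

    def test_run_length_identity(self):
        dyn = DynamicsSpec()
        ls, gt = simulate_state_sequence(dyn, 60.0, 500.0, seed=9)
        p = gt.realized
        total_s = ls.analyzed_seconds
        for c in range(4):
            if p.n_segments[c] == 0:
                continue
            lhs = p.coverage_pct[c] / 100.0 * total_s
            rhs = p.occurrence_hz[c] * (p.duration_ms[c] / 1000.0) * total_s
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_realized_matches_oracle(self):
        dyn = DynamicsSpec()
        ls, gt = simulate_state_sequence(dyn, 30.0, 250.0, seed=13)
        runs = rle_oracle(ls.labels)
        for c in range(4):
            mine = [b - a for cls, a, b in runs if cls == c]
            if mine:
                assert gt.realized.duration_ms[c] == pytest.approx(np.mean(mine) * 4.0)  # 4 ms/frame
                assert gt.realized.occurrence_hz[c] == pytest.approx(len(mine) / 30.0)

    def test_degenerate_transition_row_rejected(self):
        tr = np.zeros((4, 4))
        tr[0, 1] = 1.0
        with pytest.raises(ValueError):
            DynamicsSpec(transition=tr)

    def test_ground_truth_transition_rows(self):
        _, gt = simulate_state_sequence(DynamicsSpec(), 30.0, 500.0, seed=3)
        t = gt.realized_transition.conditional
        assert np.all(np.diag(t) == 0)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)


class TestRecordingSynthesis:
    def test_noiseless_single_state_matches_template(self, templates64):
        from mstates import LabelSequence

        n = 1000
        ls = LabelSequence(np.full(n, 2), 500.0, ((0, n),), ("A", "B", "C", "D"))
        dyn = DynamicsSpec(snr=np.inf)
        rec = synthesize_recording(templates64, ls, dyn, seed=0)
        t = np.arange(n) / 500.0
        carrier = np.sin(2 * np.pi * dyn.carrier_hz * t)
        for j in np.nonzero(np.abs(carrier) > 1e-6)[0][::97]:
            r = spatial_correlation(rec.data[:, j], templates64.maps[2])
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_snr_controls_noise_rms(self, templates64):
        from mstates import LabelSequence

        n = 4000
        ls = LabelSequence(np.zeros(n, int), 500.0, ((0, n),), ("A", "B", "C", "D"))
        rms_uv = 10.0
        rec_clean = synthesize_recording(templates64, ls, DynamicsSpec(snr=np.inf), seed=1, rms_uv=rms_uv)
        rec_noisy = synthesize_recording(templates64, ls, DynamicsSpec(snr=5.0), seed=1, rms_uv=rms_uv)
        signal_rms = np.sqrt(np.mean(rec_clean.data**2))
        noise_rms = np.sqrt(np.mean((rec_noisy.data - rec_clean.data) ** 2))
        assert signal_rms == pytest.approx(rms_uv, rel=0.05)
        assert signal_rms / noise_rms == pytest.approx(5.0, rel=0.05)

    def test_deterministic(self, templates64):
        dyn = DynamicsSpec()
        ls, _ = simulate_state_sequence(dyn, 5.0, 500.0, seed=6)
        a = synthesize_recording(templates64, ls, dyn, seed=42)
        b = synthesize_recording(templates64, ls, dyn, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            DynamicsSpec(snr=0.0)


class TestCohort:
    def test_bookkeeping(self):
        spec = CohortSpec(n_per_arm=(3, 4), length_s=6.0, sfreq=250.0, seed=1)
        cohort = simulate_cohort(spec, sequences_only=True)
        assert len(cohort.subjects) == 7
        assert len(cohort.clinical) == 7
        assert (cohort.clinical["arm"] == "patient").sum() == 3
        assert set(cohort.clinical["subject"]) == {s.subject for s in cohort.subjects}

    def test_sequences_match_full_simulation(self):
        spec = CohortSpec(n_per_arm=(2, 2), length_s=5.0, sfreq=250.0, seed=8)
        seq = simulate_cohort(spec, sequences_only=True)
        full = simulate_cohort(spec)
        for a, b in zip(seq.subjects, full.subjects):
            np.testing.assert_array_equal(a.ground_truth.labels.labels, b.ground_truth.labels.labels)
        for col in ("age", "education_years", "hama"):
            np.testing.assert_array_equal(
                seq.clinical[col].to_numpy(), full.clinical[col].to_numpy()
            )

    def test_clinical_moments_and_missingness(self):
        spec = CohortSpec(n_per_arm=(200, 5), length_s=5.0, sfreq=250.0, seed=5)
        cohort = simulate_cohort(spec, sequences_only=True)
        pat = cohort.clinical[cohort.clinical["arm"] == "patient"]
        scores = hamd24_factor_scores(pat)
        # generated at the instrument-level moments 5.50 +/- 2.61
        assert scores["anxiety_somatization"].mean() == pytest.approx(5.50, abs=0.5)
        assert scores["anxiety_somatization"].std() == pytest.approx(2.61, abs=0.6)
        assert pat["madrs"].isna().sum() == spec.clinical.madrs_missing
        ctl = cohort.clinical[cohort.clinical["arm"] == "control"]
        assert ctl["hama"].isna().all()

    def test_planted_correlation_recovered(self):
        # planted rho = 0.4 between anxiety/somatization and class-C planted
        # duration; the sample r should fall in its own Fisher-z 95% CI of
        # the target in >= 90% of replicates
        from mstates import pearson_ci_from_summary

        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            spec = CohortSpec(
                n_per_arm=(200, 1),
                length_s=5.0,
                sfreq=250.0,
                clinical=ClinicalModel(rho=0.4),
                seed=1000 + rep,
            )
            cohort = simulate_cohort(spec, sequences_only=True)
            pat = cohort.clinical[cohort.clinical["arm"] == "patient"]
            scores = hamd24_factor_scores(pat)
            r = np.corrcoef(pat["planted_duration_C"], scores["anxiety_somatization"])[0, 1]
            ci = pearson_ci_from_summary(0.4, 200)
            hits += ci.ci_low <= r <= ci.ci_high
        assert hits / n_rep >= 0.9

    def test_determinism(self):
        spec = CohortSpec(n_per_arm=(2, 1), length_s=5.0, sfreq=250.0, seed=3)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.recording.data, sb.recording.data)
        assert a.clinical.equals(b.clinical)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_arm=(0, 5))
        with pytest.raises(ValueError):
            ClinicalModel(rho=1.0)
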