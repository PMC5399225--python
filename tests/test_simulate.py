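"""Synthetic-cohort generator: determinism, planted effects, round trips."""

import numpy as np
import pandas as pd
import pytest

import batkit as bk
from batkit.io import read_cohort, write_cohort
from batkit.simulate import CohortConfig, generate_cohort


def trait_feature_corrs(sessions, traits, features, themes=(4, 7, 13)):
    """corr(latent trait, per-participant mean feature on given themes)."""
    table = bk.extract_cohort_features(sessions, treatments=False)
    df = table.data
    z = pd.Series({t.participant_id: t.security for t in traits})
    out = {}
    for feat in features:
        sub = df[(df.feature == feat) & (df.theme.isin(themes))
                 & (df.variant == "raw")]
        if sub.empty:
            continue
        m = sub.groupby("participant")["value"].mean()
        joined = pd.concat([m.rename("x"), z.rename("z")], axis=1).dropna()
        out[feat] = float(np.corrcoef(joined["x"], joined["z"])[0, 1])
    return out


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_participants=-1),
        dict(n_participants=2, n_themes=1),
        dict(n_participants=2, n_sets=4),
        dict(n_participants=2, effect_size=1.5),
        dict(n_participants=2, missingness=-0.1),
        dict(n_participants=2, exposure_s=0.0),
        dict(n_participants=2, effect_size={"bogus_modality": 0.3}),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            CohortConfig(**kw)


class TestGenerate:
    def test_empty_cohort(self):
        sessions, traits, gt = generate_cohort(
            CohortConfig(n_participants=0, n_sets=1, seed=0))
        assert sessions == [] and traits == [] and gt.empty

    def test_seed_determinism(self):
        cfg = CohortConfig(n_participants=3, n_sets=2, seed=11)
        a_sessions, a_traits, a_gt = generate_cohort(cfg)
        b_sessions, b_traits, b_gt = generate_cohort(cfg)
        assert a_traits == b_traits
        pd.testing.assert_frame_equal(a_gt, b_gt)
        for sa, sb in zip(a_sessions, b_sessions):
            np.testing.assert_array_equal(sa.ibi.intervals, sb.ibi.intervals)
            np.testing.assert_array_equal(sa.eda.values, sb.eda.values)
            pd.testing.assert_frame_equal(sa.frames, sb.frames)
            pd.testing.assert_frame_equal(sa.responses, sb.responses)

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_participants=2, n_sets=1, seed=1))[0]
        b = generate_cohort(CohortConfig(n_participants=2, n_sets=1, seed=2))[0]
        assert not np.array_equal(a[0].ibi.intervals, b[0].ibi.intervals)

    def test_streams_span_timeline_and_invariants(self, small_cohort):
        _, sessions, _, _ = small_cohort
        s = sessions[0]
        dur = s.timeline.duration_ms
        assert s.ibi.onsets[-1] >= dur - 2000.0  # last beat near the end
        assert len(s.eda) == pytest.approx(dur / 1000.0 * 4.0, abs=1)
        assert (s.frames["head_size"] > 0).all()
        liwc = [c for c in s.responses.columns if c.startswith("liwc_")]
        sums = s.responses[liwc].sum(axis=1)
        assert (sums <= 1.0 + 1e-9).all()

    def test_ground_truth_tracks_trait(self):
        _, _, gt = (c := generate_cohort(
            CohortConfig(n_participants=300, n_sets=1, seed=3,
                         ammi_coverage=1.0)))
        r = np.corrcoef(gt["latent_security"], gt["aap_security"])[0, 1]
        assert 0.6 < r < 0.95

    def test_missingness_drops_modalities(self):
        cfg = CohortConfig(n_participants=30, n_sets=1, seed=5,
                           missingness={"cardiac": 0.5})
        sessions, _, _ = generate_cohort(cfg)
        n_missing = sum(s.ibi is None for s in sessions)
        assert 5 <= n_missing <= 25
        assert all(s.eda is not None for s in sessions)


class TestPlantedEffects:
    def test_directionality_matches_schema(self):
        """Desirable features shift up with the trait, undesirable down."""
        cfg = CohortConfig(n_participants=150, n_sets=1, seed=13,
                           effect_size=0.8)
        sessions, traits, _ = generate_cohort(cfg)
        schema = bk.feature_schema()
        desirable = [f for f, m in schema.items()
                     if m["desirability"] == "desirable"]
        undesirable = [f for f, m in schema.items()
                       if m["desirability"] == "undesirable"]
        corrs = trait_feature_corrs(sessions, traits, desirable + undesirable)
        for f in desirable:
            assert corrs[f] > 0, f"desirable feature {f} planted downward"
        for f in undesirable:
            assert corrs[f] < 0, f"undesirable feature {f} planted upward"

    def test_null_effect_calibration(self):
        """With effect 0, ~5% of trait-feature correlations reject at .05."""
        from scipy import stats as st
        features = ["hrv_hf_nu", "hrv_sdnn", "mean_hr", "bayevsky_si",
                    "scr_sum", "expr_positive", "expr_negative",
                    "gaze_away_frac", "head_size_mean", "h1h2", "rd"]
        n_tests = n_sig = 0
        for seed in range(50):
            cfg = CohortConfig(n_participants=24, n_themes=6, n_sets=1,
                               seed=seed, effect_size=0.0)
            sessions, traits, _ = generate_cohort(cfg)
            table = bk.extract_cohort_features(sessions, treatments=False)
            df = table.data
            z = pd.Series({t.participant_id: t.security for t in traits})
            for feat in features:
                sub = df[(df.feature == feat) & (df.theme == 4)]
                m = sub.groupby("participant")["value"].mean()
                joined = pd.concat([m.rename("x"), z.rename("z")],
                                   axis=1).dropna()
                if len(joined) < 10:
                    continue
                p = st.pearsonr(joined["x"], joined["z"])[1]
                n_tests += 1
                n_sig += p < 0.05
        frac = n_sig / n_tests
        assert n_tests >= 500
        assert 0.02 <= frac <= 0.08, f"null rejection rate {frac:.3f}"


class TestRoundTrip:
    def test_write_then_read_equal_structures(self, tmp_path):
        cfg = CohortConfig(n_participants=2, n_sets=1, seed=21)
        sessions, traits, gt = generate_cohort(cfg)
        root = write_cohort(sessions, traits, gt, tmp_path / "cohort",
                            config=cfg)
        back, gt2, manifest = read_cohort(root)
        assert manifest["participants"] == ["p000", "p001"]
        pd.testing.assert_frame_equal(gt, gt2)
        for a, b in zip(sessions, back):
            assert a.participant_id == b.participant_id
            assert a.timeline == b.timeline
            np.testing.assert_allclose(a.ibi.onsets, b.ibi.onsets, atol=1e-9)
            np.testing.assert_allclose(a.eda.values, b.eda.values, atol=1e-12)
            assert b.eda.sample_rate == pytest.approx(a.eda.sample_rate)
            pd.testing.assert_frame_equal(a.frames, b.frames)
            pd.testing.assert_frame_equal(a.responses, b.responses)

    def test_empty_cohort_writes_manifest_only(self, tmp_path):
        root = write_cohort([], [], pd.DataFrame(), tmp_path / "empty")
        assert (root / "manifest.json").exists()
        assert sorted(p.name for p in root.iterdir()) == ["manifest.json"]

    def test_missing_modality_round_trips_as_missing(self, tmp_path):
        cfg = CohortConfig(n_participants=1, n_sets=1, seed=2)
        sessions, traits, gt = generate_cohort(cfg)
        sessions[0].eda = None
        root = write_cohort(sessions, traits, gt, tmp_path / "c")
        back, _, _ = read_cohort(root)
        assert back[0].eda is None and back[0].ibi is not None
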