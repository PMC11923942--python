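"""Gating, continuous scoring, fusion, the full screen and ranking."""

import pytest
from hypothesis import given, settings, strategies as st

import hocscreen as h
from hocscreen.screening import (
    ConfigurationError,
    isotope_gate,
    mass_gate,
    read_results,
    write_results,
)

from conftest import exact_feature


class TestMassGate:
    @pytest.mark.parametrize(
        "theoretical, measured, expected_pass",
        [
            (300.0000, 300.0012, True),   # 4.0 ppm < 5
            (300.0000, 300.0018, False),  # 6.0 ppm
            (150.0000, 150.0019, True),   # 1.9 mDa < 2 (mDa rule below 200)
            (150.0000, 150.0021, False),  # 2.1 mDa
        ],
    )
    def test_rule_selection_and_arithmetic(self, config, theoretical, measured,
                                           expected_pass):
        result = mass_gate(measured, theoretical, config)
        assert result.passed is expected_pass
        assert result.error_ppm == pytest.approx(
            (measured - theoretical) / theoretical * 1e6
        )

    def test_ppm_rule_at_exactly_boundary(self, config):
        # At 200 Da both rules coincide numerically; the ppm rule applies and
        # is the stricter one (5 ppm = 1 mDa < 2 mDa).
        assert mass_gate(200.0015, 200.0, config).passed is False
        assert mass_gate(200.0009, 200.0, config).passed is True


class TestIsotopeGate:
    def test_identical_envelope_passes_with_zero_deviation(self, config, tiny_library):
        pattern = h.isotope_pattern(tiny_library[1].formula)
        result = isotope_gate(list(pattern.peaks), pattern, config)
        assert result.passed
        assert result.gm_deviation == pytest.approx(0.0, abs=1e-9)

    def test_five_percent_deviation_fails_strict_gate(self, config):
        theory = h.isotope_pattern(h.parse_formula("Cl2"))
        base_mz = theory.base_peak_mz
        m2_mz = theory.peaks[1][0]
        # Single matched isotope at exactly 5.0% relative deviation: 64 -> 60.8.
        theory = h.IsotopePattern(((base_mz, 100.0), (m2_mz, 64.0)))
        envelope = [(base_mz, 100.0), (m2_mz, 60.8)]
        result = isotope_gate(envelope, theory, config)
        assert result.gm_deviation == pytest.approx(5.0)
        assert not result.passed

    def test_just_under_five_percent_passes(self, config):
        theory = h.isotope_pattern(h.parse_formula("Cl2"))
        envelope = [(theory.peaks[0][0], 100.0),
                    (theory.peaks[1][0], theory.peaks[1][1] * 0.951),
                    (theory.peaks[2][0], theory.peaks[2][1] * 0.951)]
        result = isotope_gate(envelope, theory, config)
        assert result.passed
        assert result.gm_deviation == pytest.approx(4.9, abs=0.01)

    def test_no_isotope_ion_observed_fails(self, config):
        theory = h.isotope_pattern(h.parse_formula("Cl2"))
        envelope = [(theory.base_peak_mz, 100.0)]  # base peak only
        assert not isotope_gate(envelope, theory, config).passed

    def test_monoisotopic_compound_bypasses(self, config):
        theory = h.isotope_pattern(h.parse_formula("P"))
        result = isotope_gate([], theory, config)
        assert result.passed and result.bypassed


class TestDeltas:
    @pytest.mark.parametrize("measured, reference, expected",
                             [(10.0, 10.0, 0.0), (10.5, 10.0, 0.5), (9.0, 10.0, -1.0)])
    def test_delta_rt_signed(self, measured, reference, expected):
        assert h.delta_rt(measured, reference) == pytest.approx(expected)

    @pytest.mark.parametrize("measured, reference, expected",
                             [(200.0, 200.0, 0.0), (204.0, 200.0, 2.0),
                              (186.0, 200.0, -7.0)])
    def test_delta_ccs_percent(self, measured, reference, expected):
        assert h.delta_ccs(measured, reference) == pytest.approx(expected)


class TestContinuousScore:
    def test_inside_high_scores_one(self):
        assert h.continuous_score(1.5, 2.0, 3.0) == 1.0

    def test_outside_low_scores_zero(self):
        assert h.continuous_score(3.5, 2.0, 3.0) == 0.0

    def test_halfway_scores_half(self):
        # Independent hand computation: (3 - 2.5) / (3 - 2) = 0.5.
        assert h.continuous_score(2.5, 2.0, 3.0) == pytest.approx(0.5)

    def test_asymmetric_intervals_decay_on_each_side(self):
        high, low = (-0.54, 0.84), (-1.23, 1.53)
        assert h.continuous_score(0.0, high, low) == 1.0
        # Positive side: (1.53 - 1.185) / (1.53 - 0.84) = 0.5.
        assert h.continuous_score(1.185, high, low) == pytest.approx(0.5)
        # Negative side: (-0.885 - (-1.23)) / (-0.54 - (-1.23)) = 0.5.
        assert h.continuous_score(-0.885, high, low) == pytest.approx(0.5)

    def test_continuity_at_boundaries(self):
        eps = 1e-9
        assert h.continuous_score(2.0 + eps, 2.0, 3.0) == pytest.approx(1.0, abs=1e-6)
        assert h.continuous_score(3.0 - eps, 2.0, 3.0) == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            h.continuous_score(1.0, 2.0, 2.0)

    @given(st.floats(-10.0, 10.0), st.floats(-10.0, 10.0))
    @settings(max_examples=100, derandomize=True)
    def test_non_increasing_beyond_high(self, a, b):
        lo, hi = sorted((abs(a) + 2.01, abs(b) + 2.01))
        if hi - lo < 1e-6:
            hi += 1e-3
        score_lo = h.continuous_score(lo, 2.0, 10.0)
        score_hi = h.continuous_score(hi, 2.0, 10.0)
        assert score_hi <= score_lo + 1e-12


class TestFuseScores:
    def test_all_perfect_gives_one(self, config):
        assert h.fuse_scores(1.0, 1.0, 1.0, config) == pytest.approx(1.0)

    def test_missing_ms2_hits_cutoff_exactly(self, config):
        fused = h.fuse_scores(1.0, 1.0, None, config)
        assert fused == pytest.approx(config.cutoff, abs=1e-12)

    def test_all_zero_gives_zero(self, config):
        assert h.fuse_scores(0.0, 0.0, 0.0, config) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_and_bounded(self, rt, ccs, ms2, bump):
        cfg = h.ScoringConfig()
        base = h.fuse_scores(rt, ccs, ms2, cfg)
        assert 0.0 <= base <= 1.0 + 1e-12
        for kwargs in ({"score_rt": min(1.0, rt + bump)},
                       {"score_ccs": min(1.0, ccs + bump)},
                       {"score_ms2": min(1.0, ms2 + bump)}):
            args = {"score_rt": rt, "score_ccs": ccs, "score_ms2": ms2, **kwargs}
            assert h.fuse_scores(cfg=cfg, **args) >= base - 1e-12


class TestScoringConfig:
    def test_defaults_match_operating_point(self, config):
        assert config.weights == (0.2, 0.4, 0.4)
        assert config.cutoff == 0.60
        assert (config.mass_tol_ppm, config.mass_tol_mda) == (5.0, 2.0)
        assert config.mass_rule_boundary == 200.0
        assert config.isotope_max_gm_deviation == 5.0
        assert config.min_isotope_ions == 1
        assert config.min_ms2_fragments_for_scoring == 2

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            h.ScoringConfig(weights=(0.5, 0.4, 0.4))

    def test_yaml_roundtrip(self, tmp_path, config):
        path = tmp_path / "config.yaml"
        config.to_yaml(path)
        loaded = h.ScoringConfig.from_yaml(path)
        assert loaded.to_dict() == config.to_dict()


class TestScreen:
    def test_exact_match_scores_one_and_is_retained(self, config, tiny_library):
        entry = tiny_library[1]
        feature = exact_feature(entry)
        score = h.MS2Score(feature.feature_id, entry.suspect_id, 1.0)
        result = h.screen([feature], [entry], [score], config)
        assert result.stage_counts == (1, 1, 1, 1)
        (candidate,) = result.candidates
        assert candidate.multidimensional_score == pytest.approx(1.0)
        assert candidate.retained and candidate.best

    def test_ccs_off_by_ten_percent_fails_ccs_stage(self, config, tiny_library):
        entry = tiny_library[1]
        feature = exact_feature(entry, ccs_measured=entry.ccs_reference * 1.10)
        result = h.screen([feature], [entry], [], config)
        assert result.stage_counts == (1, 0, 0, 0)

    def test_best_candidate_per_suspect_retained(self, config, tiny_library):
        entry = tiny_library[1]
        good = exact_feature(entry, feature_id="good")
        worse = exact_feature(
            entry, feature_id="worse",
            ccs_measured=entry.ccs_reference * 1.025,  # mid-band CCS: score 0.5
        )
        scores = [h.MS2Score("good", entry.suspect_id, 0.9),
                  h.MS2Score("worse", entry.suspect_id, 0.9)]
        result = h.screen([good, worse], [entry], scores, config)
        best = result.best_candidates
        assert [c.feature_id for c in best] == ["good"]
        assert result.stage_counts.n_above_cutoff == 2
        assert result.stage_counts.n_best_retained == 1

    def test_missing_ms2_requires_perfect_rt_and_ccs(self, config, tiny_library):
        entry = tiny_library[0]
        on_the_edge = exact_feature(entry, feature_id="edge",
                                    rt_measured=entry.rt_reference + 1.0)
        perfect = exact_feature(entry, feature_id="perfect")
        result = h.screen([on_the_edge, perfect], [entry], [], config)
        by_id = {c.feature_id: c for c in result.candidates}
        assert not by_id["edge"].retained        # RT score < 1, no MS2 to recover
        assert by_id["perfect"].retained         # exactly at the cutoff

    def test_ms2_needs_min_fragments(self, config, tiny_library):
        entry = tiny_library[0]
        feature = exact_feature(entry, ms2_fragments=[(77.0, 10.0)])
        score = h.MS2Score(feature.feature_id, entry.suspect_id, 0.99)
        result = h.screen([feature], [entry], [score], config)
        (candidate,) = result.candidates
        assert candidate.score_ms2 is None

    def test_wrong_mass_never_becomes_candidate(self, config, tiny_library):
        entry = tiny_library[0]
        feature = exact_feature(entry, mz=entry.adducts[0][1] + 0.5)
        result = h.screen([feature], [entry], [], config)
        assert result.candidates == []

    def test_empty_inputs_give_empty_result(self, config, tiny_library):
        assert h.screen([], tiny_library, [], config).candidates == []
        assert h.screen([exact_feature(tiny_library[0])], [], [], config).candidates == []

    def test_cutoff_override_honoured(self, tiny_library):
        entry = tiny_library[0]
        feature = exact_feature(entry, rt_measured=entry.rt_reference + 1.0)
        strict = h.screen([feature], [entry], [], h.ScoringConfig())
        relaxed = h.screen([feature], [entry], [],
                           h.ScoringConfig(cutoff=0.5))
        assert not strict.candidates[0].retained
        assert relaxed.candidates[0].retained


class TestRanking:
    def _candidate(self, **overrides):
        fields = dict(
            feature_id="f", suspect_id="s", matched_adduct=h.AdductKind.RADICAL_CATION,
            mass_error_ppm=1.0, mass_error_mda=0.3, isotope_gm_deviation=1.0,
            isotope_bypassed=False, delta_rt=0.1, delta_ccs=1.0, score_rt=1.0,
            score_ccs=1.0, score_ms2=None, multidimensional_score=0.6, retained=True,
        )
        fields.update(overrides)
        return h.CandidateMatch(**fields)

    def test_descending_by_score(self):
        result = h.ScreeningResult(
            [self._candidate(suspect_id="a", multidimensional_score=0.6),
             self._candidate(suspect_id="b", multidimensional_score=0.8)],
            h.StageCounts(2, 2, 2, 2),
        )
        assert [c.suspect_id for c in h.rank_candidates(result)] == ["b", "a"]

    def test_tie_broken_by_smaller_ccs_deviation(self):
        result = h.ScreeningResult(
            [self._candidate(suspect_id="a", delta_ccs=2.0),
             self._candidate(suspect_id="b", delta_ccs=-1.0)],
            h.StageCounts(2, 2, 2, 2),
        )
        assert [c.suspect_id for c in h.rank_candidates(result)] == ["b", "a"]

    def test_full_tie_broken_by_suspect_id(self):
        result = h.ScreeningResult(
            [self._candidate(suspect_id="b"), self._candidate(suspect_id="a")],
            h.StageCounts(2, 2, 2, 2),
        )
        assert [c.suspect_id for c in h.rank_candidates(result)] == ["a", "b"]


class TestResultIO:
    def test_roundtrip_preserves_candidates_and_counts(self, tmp_path, config,
                                                       tiny_library):
        features = [exact_feature(entry) for entry in tiny_library]
        scores = [h.MS2Score(f.feature_id, e.suspect_id, 0.8)
                  for f, e in zip(features, tiny_library)]
        result = h.screen(features, tiny_library, scores, config)
        path = tmp_path / "candidates.csv"
        write_results(result, path)
        loaded = read_results(path)
        assert loaded.stage_counts == result.stage_counts
        original = {(c.feature_id, c.suspect_id): c for c in result.candidates}
        for candidate in loaded.candidates:
            twin = original[(candidate.feature_id, candidate.suspect_id)]
            assert candidate.multidimensional_score == pytest.approx(
                twin.multidimensional_score, abs=1e-12
            )
            assert candidate.retained == twin.retained
            assert candidate.best == twin.best
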