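import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_at_content, brute_gc_skew, brute_window_mean
from structatlas.scales import load_builtin_scale, straight_model
from structatlas.seqio import SequenceRecord, reverse_complement
from structatlas.tracks import (Track, WindowSpec, at_content_track,
                                curvature_profile, curvature_track,
                                expected_count, gc_content_track,
                                gc_skew_track, position_preference_track,
                                stacking_energy_track, windowed_mean)

dna = st.text(alphabet="ACGT", min_size=20, max_size=200)
nan = float("nan")


class TestWindowedMean:
    def test_constant_profile(self):
        t = windowed_mean([1, 1, 1, 1], WindowSpec(2, 1))
        np.testing.assert_array_equal(t.values, [1, 1, 1])

    def test_arithmetic_mean(self):
        t = windowed_mean([0, 2], WindowSpec(2))
        np.testing.assert_array_equal(t.values, [1])

    def test_nan_excluded_from_mean(self):
        t = windowed_mean([1, nan, 3], WindowSpec(3))
        np.testing.assert_array_equal(t.values, [2])

    def test_all_nan_window_is_nan(self):
        t = windowed_mean([nan, nan, 1.0], WindowSpec(2))
        assert np.isnan(t.values[0])
        assert t.values[1] == 1.0

    def test_window_exceeding_profile_errors(self):
        with pytest.raises(ValueError, match="window exceeds sequence"):
            windowed_mean([1, 2], WindowSpec(3))

    def test_window_centered_start_offset(self):
        t = windowed_mean(np.zeros(50), WindowSpec(10, 2))
        assert t.start_offset == 5
        assert t.positions[0] == 5 and t.positions[1] == 7

    @settings(max_examples=40, deadline=None)
    @given(st.integers(1, 30), st.integers(1, 7), st.integers(0, 1000))
    def test_matches_brute_force_oracle(self, window, step, seed):
        rng = np.random.default_rng(seed)
        profile = rng.normal(size=window + rng.integers(0, 60))
        profile[rng.random(len(profile)) < 0.15] = nan
        t = windowed_mean(profile, WindowSpec(window, step))
        expected = brute_window_mean(list(profile), window, step)
        assert len(t) == expected_count(len(profile), window, step)
        np.testing.assert_allclose(t.values, expected, atol=1e-9)


class TestPropertyTracks:
    def test_polya_stacking_is_scale_entry(self):
        s = load_builtin_scale("stacking_energy")
        t = stacking_energy_track(SequenceRecord("a", "A" * 50), WindowSpec(10))
        np.testing.assert_allclose(t.values, s.values["AA"])
        assert t.units == "kcal/mol"

    def test_polya_position_preference_is_scale_entry(self):
        s = load_builtin_scale("position_preference")
        t = position_preference_track(SequenceRecord("a", "A" * 50), WindowSpec(10))
        np.testing.assert_allclose(t.values, s.values["AAA"])

    def test_all_n_window_is_nan(self):
        t = position_preference_track(SequenceRecord("a", "N" * 30 + "ACGT" * 10),
                                      WindowSpec(10))
        assert np.isnan(t.values[0])
        assert np.isfinite(t.values[-1])

    def test_stacking_track_of_revcomp_is_reversed(self, random_seq):
        seq = random_seq(400)
        rc = SequenceRecord("rc", reverse_complement(seq.seq))
        spec = WindowSpec(25, 1)
        fwd = stacking_energy_track(seq, spec).values
        rev = stacking_energy_track(rc, spec).values
        np.testing.assert_allclose(rev, fwd[::-1], atol=1e-12)

    @pytest.mark.parametrize("window,step", [(7, 1), (100, 13), (64, 64)])
    def test_brute_force_equivalence_random_1kb(self, random_seq, window, step):
        seq = random_seq(1000)
        s = load_builtin_scale("stacking_energy")
        from structatlas.scales import lookup_profile
        prof = lookup_profile(seq, s)
        t = stacking_energy_track(seq, WindowSpec(window, step))
        np.testing.assert_allclose(
            t.values, brute_window_mean(list(prof), window, step), atol=1e-9)


class TestCurvature:
    def test_straight_model_gives_identically_zero(self, random_seq):
        seq = random_seq(500)
        t = curvature_track(seq, model=straight_model(), spec=WindowSpec(30))
        np.testing.assert_allclose(t.values, 0.0, atol=1e-12)

    def test_phased_a_tracts_exceed_shuffled_control(self, rng):
        from structatlas.fixtures import Block, FixtureRecipe, make_sequence
        recipe = FixtureRecipe(length=800, seed=11, blocks=(
            Block("phased_a_tract", 100, 700),))
        phased = make_sequence(recipe)
        shuffled = "".join(rng.permutation(list(phased.seq)))
        control = SequenceRecord("shuf", shuffled)
        spec = WindowSpec(50)
        c_phased = np.nanmean(curvature_track(phased, spec=spec).values[100:600])
        c_control = np.nanmean(curvature_track(control, spec=spec).values[100:600])
        assert c_phased > c_control

    def test_homopolymer_curvature_translation_invariant(self):
        seq = SequenceRecord("a", "A" * 120)
        prof = curvature_profile(seq, load_builtin_scale("curvature"))
        np.testing.assert_allclose(prof, prof[0], atol=1e-9)

    def test_curvature_nonnegative(self, random_seq):
        t = curvature_track(random_seq(600), spec=WindowSpec(40))
        assert np.all(t.values[np.isfinite(t.values)] >= 0)

    def test_n_windows_are_nan(self):
        seq = SequenceRecord("a", "ACGT" * 20 + "N" * 40 + "ACGT" * 20)
        prof = curvature_profile(seq, load_builtin_scale("curvature"))
        assert np.isnan(prof[70])
        assert np.isfinite(prof[0])


class TestGcSkewAtContent:
    def test_all_g_window_is_plus_one(self):
        t = gc_skew_track(SequenceRecord("a", "G" * 40), WindowSpec(10))
        np.testing.assert_array_equal(t.values, 1.0)

    def test_balanced_gc_window_is_zero(self):
        t = gc_skew_track(SequenceRecord("a", "GGCC" * 10), WindowSpec(4, 4))
        np.testing.assert_array_equal(t.values, 0.0)

    def test_no_gc_window_is_nan(self):
        t = gc_skew_track(SequenceRecord("a", "ATAT" * 10), WindowSpec(8))
        assert np.all(np.isnan(t.values))

    def test_per_window_length_normalisation_option(self):
        t = gc_skew_track(SequenceRecord("a", "GGAT" * 10), WindowSpec(4, 4),
                          per_window_length=True)
        np.testing.assert_allclose(t.values, 0.5)

    def test_at_only_is_one_gc_only_is_zero(self):
        assert np.all(at_content_track(SequenceRecord("a", "ATAT" * 10),
                                       WindowSpec(5)).values == 1.0)
        assert np.all(at_content_track(SequenceRecord("a", "GCGC" * 10),
                                       WindowSpec(5)).values == 0.0)

    def test_n_counts_in_denominator_only(self):
        t = at_content_track(SequenceRecord("a", "ATNN" * 5), WindowSpec(4, 4))
        np.testing.assert_allclose(t.values, 0.5)

    @settings(max_examples=80, deadline=None)
    @given(dna, st.integers(2, 40), st.integers(1, 9))
    def test_skew_antisymmetry_and_content_complement(self, seq, window, step):
        window = min(window, len(seq))
        rec = SequenceRecord("h", seq)
        rc = SequenceRecord("rc", reverse_complement(seq))
        spec = WindowSpec(window, step)
        skew = gc_skew_track(rec, spec).values
        assert np.all((skew[np.isfinite(skew)] >= -1)
                      & (skew[np.isfinite(skew)] <= 1))
        # antisymmetry only has aligned windows when step divides the slack
        if (len(seq) - window) % step == 0:
            skew_rc = gc_skew_track(rc, spec).values
            np.testing.assert_allclose(skew_rc, -skew[::-1], atol=1e-12)
        at = at_content_track(rec, spec).values
        gc = gc_content_track(rec, spec).values
        np.testing.assert_allclose(at + gc, 1.0, atol=1e-12)
        np.testing.assert_allclose(at, brute_at_content(seq, window, step),
                                   atol=1e-12)
        np.testing.assert_allclose(skew, brute_gc_skew(seq, window, step),
                                   atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(dna, st.integers(1, 50), st.integers(1, 11))
    def test_track_count_invariant(self, seq, window, step):
        window = min(window, len(seq))
        t = at_content_track(SequenceRecord("h", seq), WindowSpec(window, step))
        assert len(t) == expected_count(len(seq), window, step)
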