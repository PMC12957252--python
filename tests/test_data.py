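"""Container I/O, sliding windows, and leakage-free normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dspmcf import FeatureDataset, SubjectRecord, Normalizer, sliding_windows, save, load, normalize
from dspmcf.data import FormatError


def _record(sid, n=4, T=6, C=5, B=3, n_classes=3, seed=0):
    rng = np.random.default_rng(seed + sid)
    return SubjectRecord(sid, rng.normal(size=(n, T, C, B)), rng.integers(n_classes, size=n))


class TestSlidingWindows:
    def test_single_window_identity(self, rng):
        series = rng.normal(size=(30, 4, 2))
        wins = sliding_windows(series, T=30, stride=1)
        assert wins.shape == (1, 30, 4, 2)
        np.testing.assert_array_equal(wins[0], series)

    def test_count_formula_example(self, rng):
        wins = sliding_windows(rng.normal(size=(12, 3, 2)), T=10, stride=1)
        assert len(wins) == 3

    @pytest.mark.parametrize("T", [30, 10])
    def test_profile_window_lengths_accepted(self, rng, T):
        wins = sliding_windows(rng.normal(size=(40, 4, 5)), T=T, stride=3)
        assert wins.shape[1] == T

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            sliding_windows(rng.normal(size=(5, 3, 2)), T=6)

    @settings(max_examples=40, deadline=None)
    @given(L=st.integers(1, 40), T=st.integers(1, 40), stride=st.integers(1, 5))
    def test_count_matches_brute_force(self, L, T, stride):
        series = np.arange(L * 2.0).reshape(L, 1, 2)
        if L < T:
            with pytest.raises(ValueError):
                sliding_windows(series, T, stride)
            return
        wins = sliding_windows(series, T, stride)
        brute = [series[s : s + T] for s in range(0, L - T + 1) if s % stride == 0]
        assert len(wins) == len(brute) == (L - T) // stride + 1
        for w, b in zip(wins, brute):
            np.testing.assert_array_equal(w, b)


class TestContainer:
    def test_round_trip_exact(self, tmp_path):
        ds = FeatureDataset([_record(0), _record(1)], n_classes=3)
        save(ds, tmp_path / "x.h5")
        back = load(tmp_path / "x.h5")
        for a, b in zip(ds.subjects, back.subjects):
            np.testing.assert_array_equal(a.features, b.features)
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_missing_labels_rejected(self, tmp_path):
        import h5py

        ds = FeatureDataset([_record(0)], n_classes=3)
        p = tmp_path / "x.h5"
        save(ds, p)
        with h5py.File(p, "r+") as f:
            del f["subject_0/labels"]
        with pytest.raises(FormatError):
            load(p)

    def test_unknown_schema_rejected(self, tmp_path):
        import h5py

        p = tmp_path / "x.h5"
        with h5py.File(p, "w") as f:
            f.create_group("meta").attrs["schema"] = "something-else"
        with pytest.raises(FormatError):
            load(p)

    def test_shape_mismatch_across_subjects_rejected(self):
        with pytest.raises(FormatError):
            FeatureDataset([_record(0, T=6), _record(1, T=7)], n_classes=3)

    def test_duplicate_subject_ids_rejected(self):
        with pytest.raises(FormatError):
            FeatureDataset([_record(0), _record(0)], n_classes=3)

    def test_empty_subject_rejected(self):
        with pytest.raises(FormatError):
            SubjectRecord(0, np.zeros((0, 4, 3, 2)), np.zeros(0, dtype=int))


class TestNormalize:
    def test_mode_none_is_identity(self):
        ds = FeatureDataset([_record(0)], n_classes=3)
        out, norm = normalize(ds, mode="none")
        assert norm is None
        np.testing.assert_array_equal(out.subjects[0].features, ds.subjects[0].features)

    def test_zscore_moments_on_source_pool(self):
        ds = FeatureDataset([_record(0, n=50), _record(1, n=50)], n_classes=3)
        out, _ = normalize(ds)
        stacked = np.concatenate([s.features for s in out.subjects])
        np.testing.assert_allclose(stacked.mean(axis=(0, 1)), 0.0, atol=1e-10)
        np.testing.assert_allclose(stacked.std(axis=(0, 1)), 1.0, atol=1e-10)

    def test_zero_variance_feature_floored(self):
        feats = np.ones((5, 4, 3, 2))
        ds = FeatureDataset([SubjectRecord(0, feats, np.zeros(5, dtype=int))], n_classes=3)
        out, norm = normalize(ds)
        assert np.all(norm.sd >= 1e-6)
        assert np.all(np.isfinite(out.subjects[0].features))

    def test_target_subject_never_enters_fit(self):
        """Fitting with and without the target present must be identical."""
        source = FeatureDataset([_record(0, n=30), _record(1, n=30)], n_classes=3)
        with_target = FeatureDataset(
            [_record(0, n=30), _record(1, n=30), _record(2, n=30, seed=77)], n_classes=3
        )
        norm_source = Normalizer.fit(source)
        norm_source2 = Normalizer.fit(with_target.subset([0, 1]))
        np.testing.assert_array_equal(norm_source.mean, norm_source2.mean)
        np.testing.assert_array_equal(norm_source.sd, norm_source2.sd)
        # and the fit does change if the target were (wrongly) included
        norm_leaky = Normalizer.fit(with_target)
        assert not np.array_equal(norm_source.mean, norm_leaky.mean)
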