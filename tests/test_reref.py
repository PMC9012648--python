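"""Reference reconstructions: definitions, invariances, REST recovery, and
the scikit-learn transformer surface."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from abrreref.forward import HeadModel, compute_lead_field, dipole_gains, fibonacci_source_layer
from abrreref.montage import dense_montage
from abrreref.reref import (
    AverageReference,
    MeanMastoidReference,
    RESTReference,
    build_rest_transform,
    to_average_reference,
    to_mean_mastoid,
    to_rest,
)


class TestAverageReference:
    def test_definition_on_column(self):
        out = to_average_reference(np.array([[1.0], [2.0], [3.0]]))
        assert np.array_equal(out, [[-1.0], [0.0], [1.0]])

    def test_idempotent(self, rng):
        x = rng.standard_normal((6, 50))
        once = to_average_reference(x)
        assert np.allclose(to_average_reference(once), once)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="two channels"):
            to_average_reference(np.ones((1, 10)))

    @settings(max_examples=30, deadline=None)
    @given(arrays(np.float64, (4, 7),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    def test_column_means_vanish(self, x):
        out = to_average_reference(x)
        assert np.all(np.abs(out.mean(axis=0)) <= 1e-9 * (1 + np.abs(x).max()))


class TestMeanMastoid:
    def test_definition_on_toy(self):
        data = np.array([[10.0], [2.0], [4.0]])
        out = to_mean_mastoid(data, ["Cz", "M1", "M2"])
        assert out[0, 0] == 7.0

    def test_mastoid_mean_is_zero_after(self, rng):
        data = rng.standard_normal((5, 30))
        names = ["A", "B", "C", "M1", "M2"]
        out = to_mean_mastoid(data, names)
        assert np.allclose(0.5 * (out[3] + out[4]), 0, atol=1e-12)

    def test_idempotent(self, rng):
        data = rng.standard_normal((4, 20))
        names = ["A", "B", "M1", "M2"]
        once = to_mean_mastoid(data, names)
        assert np.allclose(to_mean_mastoid(once, names), once)

    def test_missing_mastoid_rejected(self):
        with pytest.raises(KeyError, match="M2"):
            to_mean_mastoid(np.zeros((2, 3)), ["Cz", "M1"])


class TestRESTTransform:
    def test_common_mode_annihilated(self, recording_leadfield):
        t = build_rest_transform(recording_leadfield)
        ones = np.ones(t.matrix.shape[1])
        assert np.linalg.norm(t.matrix @ ones) < 1e-6 * np.linalg.norm(t.matrix)

    def test_channel_permutation_consistency(self, recording_leadfield):
        t = build_rest_transform(recording_leadfield)
        perm = np.random.default_rng(0).permutation(len(t.channel_names))
        shuffled = recording_leadfield.subset(
            [recording_leadfield.channel_names[i] for i in perm])
        t_perm = build_rest_transform(shuffled)
        assert np.allclose(t_perm.matrix, t.matrix[np.ix_(perm, perm)], atol=1e-9)

    def test_idempotent_within_truncation(self, recording_leadfield, rng):
        t = build_rest_transform(recording_leadfield)
        x = rng.standard_normal((len(t.channel_names), 40))
        once = to_rest(x, t)
        twice = to_rest(once, t)
        assert np.max(np.abs(twice - once)) < 1e-9 * np.max(np.abs(once))

    def test_invariant_to_any_common_waveform(self, recording_leadfield, rng):
        t = build_rest_transform(recording_leadfield)
        x = rng.standard_normal((len(t.channel_names), 40))
        common = rng.standard_normal(40)
        a = to_rest(x, t)
        b = to_rest(x + common, t)
        assert np.max(np.abs(a - b)) < 1e-9

    def test_rank_deficient_leadfield_warns(self, recording_leadfield):
        bad = recording_leadfield.subset(list(recording_leadfield.channel_names))
        dup = np.array(bad.matrix)
        dup[1] = dup[0]  # two identical channels: extra rank loss
        from abrreref.forward import LeadField

        lf = LeadField(dup, bad.channel_names, "dup")
        with pytest.warns(RuntimeWarning, match="conditioned"):
            build_rest_transform(lf)


class TestRESTRecovery:
    """Forward-model oracle: generate infinity data, centre, standardise."""

    def _mean_recovery_error(self, leadfield, n_probe=60, seed=5):
        t = build_rest_transform(leadfield)
        rng = np.random.default_rng(seed)
        errs = []
        for _ in range(n_probe):
            s = rng.integers(leadfield.n_sources)
            v = leadfield.gains(s) @ rng.standard_normal(3)
            rec = to_rest(v[:, None], t)[:, 0]
            errs.append(np.linalg.norm(rec - v) / np.linalg.norm(v))
        return float(np.mean(errs))

    def test_error_decreases_with_montage_density(self, recording_leadfield,
                                                  head, source_layer):
        lf128 = compute_lead_field(dense_montage(128), head, source_layer)
        err32 = self._mean_recovery_error(recording_leadfield)
        err128 = self._mean_recovery_error(lf128)
        assert err128 < err32

    def test_recovery_error_is_pure_common_mode(self, recording_leadfield, rng):
        # the residual of REST recovery is a channel-constant offset
        t = build_rest_transform(recording_leadfield)
        s = int(rng.integers(recording_leadfield.n_sources))
        v = recording_leadfield.gains(s) @ rng.standard_normal(3)
        resid = to_rest(v[:, None], t)[:, 0] - v
        assert np.std(resid) < 1e-8 * np.max(np.abs(resid) + 1e-30)

    def test_deep_abr_source_recovered_at_cz(self, montage, head, recording_leadfield):
        # the pipeline's guarantee: the brainstem generator's Cz potential
        # survives REST standardisation to within 5%
        g = dipole_gains(montage.recording_channels, head,
                         [0.0, 0.02, 0.01], [0.0, 0.2873, 0.9578])[:, 0]
        t = build_rest_transform(recording_leadfield)
        rec = to_rest(g[:, None], t)[:, 0]
        i_cz = recording_leadfield.channel_names.index("Cz")
        assert abs(rec[i_cz] - g[i_cz]) / abs(g[i_cz]) < 0.05


class TestSklearnSurface:
    def test_average_reference_matches_function(self, rng):
        x = rng.standard_normal((100, 6))
        est = AverageReference().fit(x)
        assert np.allclose(est.transform(x), to_average_reference(x.T).T)
        assert est.matrix_.shape == (6, 6)

    def test_mean_mastoid_matches_function(self, rng):
        names = ["Cz", "Pz", "M1", "M2"]
        x = rng.standard_normal((50, 4))
        est = MeanMastoidReference(names).fit(x)
        assert np.allclose(est.transform(x), to_mean_mastoid(x.T, names).T)

    def test_rest_matches_function(self, recording_leadfield, rng):
        x = rng.standard_normal((30, len(recording_leadfield.channel_names)))
        est = RESTReference(recording_leadfield).fit(x)
        t = build_rest_transform(recording_leadfield)
        assert np.allclose(est.transform(x), to_rest(x.T, t).T, atol=1e-10)

    def test_get_params_and_clone(self, recording_leadfield):
        est = MeanMastoidReference(["A", "M1", "M2"], m1="M1", m2="M2")
        assert est.get_params()["m1"] == "M1"
        clone(est)
        clone(RESTReference(recording_leadfield, svd_rtol=1e-5))

    def test_composes_in_sklearn_pipeline(self, rng):
        from abrreref.preprocess import ButterworthBandpass

        x = rng.standard_normal((4000, 5))
        pipe = Pipeline([
            ("bp", ButterworthBandpass(fs_hz=20000.0)),
            ("ar", AverageReference()),
        ])
        out = pipe.fit_transform(x)
        assert out.shape == x.shape
        assert np.allclose(out.mean(axis=1), 0, atol=1e-9)

    def test_channel_count_mismatch_rejected(self, rng):
        est = AverageReference().fit(rng.standard_normal((10, 4)))
        with pytest.raises(ValueError):
            est.transform(rng.standard_normal((10, 5)))
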