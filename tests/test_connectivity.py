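"""Connectivity measures: Pearson/partial formulas and tangent geometry."""

import numpy as np
import pytest

from neurowalk.types import ROITimeSeries
from neurowalk.connectivity import (
    ConnectivityExtractor,
    expm_sym,
    fit_tangent_reference,
    logm_spd,
    partial_connectivity,
    pearson_connectivity,
    subject_covariance,
    tangent_connectivity,
    tangent_to_covariance,
)


def _ts(data, sid="s"):
    return ROITimeSeries(subject_id=sid, site_id="x", label="unknown", data=np.asarray(data, float))


def random_spd(n, rng, cond=10.0):
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    w = np.exp(rng.uniform(0, np.log(cond), n))
    return (q * w) @ q.T


class TestPearson:
    def test_perfect_linear_dependence(self):
        cm = pearson_connectivity(_ts([[1, 2], [2, 4], [3, 6], [4, 8]]))
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        cm = pearson_connectivity(_ts([[1, 4], [2, 3], [3, 2], [4, 1]]))
        assert cm.values[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, random_ts):
        cm = pearson_connectivity(random_ts)
        x = random_ts.data - random_ts.data.mean(axis=0)
        cov = x.T @ x / x.shape[0]
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        assert np.allclose(cm.values, expected, atol=1e-12)

    def test_zero_variance_column_names_roi(self):
        data = np.ones((10, 3))
        data[:, 0] = np.arange(10)
        data[:, 2] = np.arange(10) ** 2
        with pytest.raises(ValueError, match=r"\[1\]"):
            pearson_connectivity(_ts(data))


class TestPartial:
    def test_two_rois_equals_pearson(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((200, 2))
        p = partial_connectivity(_ts(data), shrinkage=None).values
        r = pearson_connectivity(_ts(data)).values
        assert p[0, 1] == pytest.approx(r[0, 1], abs=1e-10)

    def test_chain_conditional_independence(self):
        # X -> Y -> Z: partial corr of (X, Z) given Y vanishes
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        y = x + 0.5 * rng.standard_normal(5000)
        z = y + 0.5 * rng.standard_normal(5000)
        p = partial_connectivity(_ts(np.column_stack([x, y, z])), shrinkage=None).values
        assert abs(p[0, 2]) < 0.05

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        p = partial_connectivity(_ts(rng.standard_normal((5000, 5))), shrinkage=None).values
        off = p[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_singular_without_shrinkage_fails(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="shrinkage"):
            partial_connectivity(_ts(rng.standard_normal((5, 8))), shrinkage=None)


class TestTangentReference:
    def test_identical_inputs_fixed_point(self):
        rng = np.random.default_rng(4)
        sigma = random_spd(5, rng)
        ref = fit_tangent_reference([sigma] * 4)
        assert np.allclose(ref.reference, sigma, atol=1e-8)

    def test_commuting_diagonal_closed_form(self):
        d1 = np.diag([1.0, 2.0, 3.0])
        d2 = np.diag([4.0, 0.5, 3.0])
        ref = fit_tangent_reference([d1, d2])
        expected = np.diag(np.sqrt(np.diag(d1) * np.diag(d2)))
        assert np.allclose(ref.reference, expected, atol=1e-7)

    def test_geometric_mean_scale_symmetry(self):
        rng = np.random.default_rng(5)
        sigma = random_spd(4, rng)
        c = 3.0
        ref = fit_tangent_reference([c * sigma, sigma / c])
        assert np.allclose(ref.reference, sigma, atol=1e-6)

    def test_whitener_inverts_reference(self):
        rng = np.random.default_rng(6)
        ref = fit_tangent_reference([random_spd(6, rng) for _ in range(5)])
        eye = ref.whitener @ ref.reference @ ref.whitener.T
        assert np.allclose(eye, np.eye(6), atol=1e-8)

    def test_non_spd_input_names_subject(self):
        bad = -np.eye(3)
        with pytest.raises(ValueError, match="sub_b"):
            fit_tangent_reference([np.eye(3), bad], subject_ids=["sub_a", "sub_b"])

    def test_matches_nilearn_geometric_mean(self):
        nilearn_cm = pytest.importorskip("nilearn.connectome")
        rng = np.random.default_rng(7)
        data = [rng.standard_normal((100, 5)) for _ in range(6)]
        covs = [subject_covariance(x) for x in data]
        ref = fit_tangent_reference(covs)
        from nilearn.connectome.connectivity_matrices import _geometric_mean

        expected = _geometric_mean([c.copy() for c in covs], max_iter=200, tol=1e-10)
        assert np.allclose(ref.reference, expected, atol=1e-5)


class TestTangentMap:
    def test_reference_maps_to_zero(self):
        rng = np.random.default_rng(8)
        sigma = random_spd(5, rng)
        ref = fit_tangent_reference([sigma])
        t = tangent_connectivity(sigma, ref)
        assert np.max(np.abs(t.values)) < 1e-8

    def test_scaled_reference_maps_to_log_c_identity(self):
        rng = np.random.default_rng(9)
        sigma = random_spd(5, rng)
        ref = fit_tangent_reference([sigma])
        t = tangent_connectivity(2.5 * sigma, ref)
        assert np.allclose(t.values, np.log(2.5) * np.eye(5), atol=1e-6)

    def test_matches_eigendecomposition_logm_oracle(self):
        rng = np.random.default_rng(10)
        ref = fit_tangent_reference([random_spd(6, rng) for _ in range(3)])
        sigma = random_spd(6, rng)
        t = tangent_connectivity(sigma, ref)
        m = ref.whitener @ sigma @ ref.whitener.T
        w, v = np.linalg.eigh((m + m.T) / 2)
        oracle = (v * np.log(w)) @ v.T
        assert np.allclose(t.values, oracle, atol=1e-8)

    def test_round_trip_recovers_subject_covariance(self):
        rng = np.random.default_rng(11)
        covs = [random_spd(5, rng) for _ in range(20)]
        ref = fit_tangent_reference(covs)
        for c in covs:
            t = tangent_connectivity(c, ref)
            back = tangent_to_covariance(t.values, ref)
            assert np.max(np.abs(back - c)) < 1e-6

    def test_non_spd_subject_fails(self):
        ref = fit_tangent_reference([np.eye(3)])
        with pytest.raises(ValueError, match="positive definite"):
            tangent_connectivity(np.diag([1.0, -1.0, 1.0]), ref)


class TestExtractor:
    def test_outputs_symmetric_and_bounded(self, small_cohort):
        subs = small_cohort.subjects[:6]
        for kind in ("pearson", "partial", "tangent"):
            ext = ConnectivityExtractor(kind=kind).fit(subs)
            for cm in ext.transform(subs):
                assert np.allclose(cm.values, cm.values.T, atol=1e-10)
                if kind != "tangent":
                    assert np.all(np.abs(cm.values) <= 1 + 1e-12)

    def test_reference_independent_of_test_subjects(self, small_cohort):
        train = small_cohort.subjects[:6]
        ext = ConnectivityExtractor(kind="tangent").fit(train)
        ref_before = ext.reference_.reference.copy()
        ext.transform(small_cohort.subjects[6:10])  # unseen subjects
        assert np.array_equal(ext.reference_.reference, ref_before)
        assert set(ext.fit_subjects_) == {s.subject_id for s in train}
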