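"""Facial signatures, normal equivalents, and morphs."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from facegrowth import (
    CorrespondedShape,
    centroid_size,
    closest_control,
    export_signature_colormap,
    facial_signature,
    make_morph,
    normal_equivalent,
    simulate_patient,
)
from facegrowth.assess import align_to_expected, signature_from_entry
from facegrowth.errors import ValidationError
from facegrowth.mesh import read_ply
from facegrowth.simulate import base_topology, bump_field, ground_truth
from facegrowth.variation import SSM

from conftest import random_rigid


def _toy_ssm(rng, k=30, m=4):
    modes, _ = np.linalg.qr(rng.standard_normal((3 * k, m)))
    lam = np.sort(rng.uniform(0.5, 5.0, m))[::-1]
    return SSM(modes=modes.T, mode_variances=lam, retained_fraction=0.98,
               n_effective=50.0, total_variance=lam.sum() / 0.9)


class TestFacialSignature:
    def test_expected_face_has_zero_signature(self, full_model):
        entry = full_model.entries[1]
        sig = facial_signature(entry.expected, full_model, age=entry.age)
        assert np.nanmax(np.abs(sig.z_normal)) < 1e-8
        assert np.nanmax(np.abs(sig.z_ml)) < 1e-8
        assert np.nanmax(sig.z_magnitude) < 1e-8

    def test_constructed_two_sd_outward_displacement(self, full_model):
        """Patient = expected + 2 sd_normal * normal at one vertex."""
        entry = full_model.entries[0]
        v = 137
        patient = entry.expected.copy()
        patient[v] += 2.0 * entry.sd.sd_normal[v] * entry.normals[v]
        sig = signature_from_entry(patient, entry, full_model, entry.age)
        assert sig.z_normal[v] == pytest.approx(2.0, abs=1e-9)
        others = np.delete(sig.z_normal, v)
        assert np.nanmax(np.abs(others)) < 1e-9

    def test_signature_linearity_in_displacement(self, full_model):
        entry = full_model.entries[0]
        rng = np.random.default_rng(1)
        disp = rng.standard_normal(entry.expected.shape)
        s1 = signature_from_entry(entry.expected + disp, entry, full_model, entry.age)
        s3 = signature_from_entry(entry.expected + 3 * disp, entry, full_model, entry.age)
        np.testing.assert_allclose(s3.z_normal, 3 * s1.z_normal, rtol=1e-9)
        np.testing.assert_allclose(s3.z_ap, 3 * s1.z_ap, rtol=1e-9)

    def test_alignment_removes_patient_pose(self, full_model, rng):
        entry = full_model.entries[1]
        R, t = random_rigid(rng, max_angle=np.pi / 6)
        posed = entry.expected @ R + t
        sig = facial_signature(posed, full_model, age=entry.age)
        assert np.nanmax(np.abs(sig.z_normal)) < 1e-6

    def test_sex_mismatch_rejected(self, full_model):
        entry = full_model.entries[0]
        with pytest.raises(ValidationError):
            facial_signature(entry.expected, full_model, age=entry.age, sex="male")

    def test_bump_patient_flags_bump_region(self, full_spec, full_model):
        """A 3-SD outward bump is flagged at |z| > 2 exactly on its support."""
        field = bump_field(full_spec)
        age = 30.0
        patient = simulate_patient(full_spec, age, dysmorphism_field=field,
                                   amplitude_in_sd=3.0, variation_scale=0.0)
        sig = facial_signature(patient, full_model)
        true_support = 3.0 * field >= 2.0
        detected = np.abs(sig.z_normal) > 2.0
        jaccard = (detected & true_support).sum() / (detected | true_support).sum()
        assert jaccard > 0.8


class TestNormalEquivalent:
    def test_in_span_patient_is_returned_unchanged(self, rng):
        ssm = _toy_ssm(rng)
        expected = rng.standard_normal((30, 3))
        c = 0.3 * np.sqrt(ssm.mode_variances)  # D^2 well below critical
        patient = expected + ssm.reconstruct(c).reshape(30, 3)
        ne = normal_equivalent(patient, ssm, expected)
        assert np.sqrt(np.mean((ne.vertices - patient) ** 2)) < 1e-6
        assert ne.tail_probability > 0.05

    def test_extreme_patient_lands_on_mahalanobis_boundary(self, rng):
        ssm = _toy_ssm(rng)
        expected = rng.standard_normal((30, 3))
        c = 10.0 * np.sqrt(ssm.mode_variances)
        patient = expected + ssm.reconstruct(c).reshape(30, 3)
        ne = normal_equivalent(patient, ssm, expected)
        d2_crit = stats.chi2.ppf(0.95, ssm.n_modes)
        assert ne.mahalanobis_sq == pytest.approx(d2_crit, rel=1e-12)
        assert ne.tail_probability == pytest.approx(0.05, abs=1e-9)

    def test_final_d2_never_exceeds_critical(self, rng):
        ssm = _toy_ssm(rng)
        expected = rng.standard_normal((30, 3))
        d2_crit = stats.chi2.ppf(0.95, ssm.n_modes)
        for _ in range(10):
            patient = expected + rng.standard_normal((30, 3)) * rng.uniform(0.1, 5)
            ne = normal_equivalent(patient, ssm, expected)
            assert ne.mahalanobis_sq <= d2_crit + 1e-9

    def test_single_iteration_equals_closest_control(self, rng):
        ssm = _toy_ssm(rng)
        expected = rng.standard_normal((30, 3))
        for _ in range(20):
            patient = expected + rng.standard_normal((30, 3)) * rng.uniform(0.2, 4)
            a = normal_equivalent(patient, ssm, expected, max_iter=1,
                                  update_weights=False)
            b = closest_control(patient, ssm, expected)
            assert np.sqrt(np.mean((a.vertices - b.vertices) ** 2)) < 1e-8

    def test_closest_control_matches_constrained_projection_oracle(self, rng):
        """KKT oracle: minimize the standardized distance to the projection
        subject to D^2 <= critical, solved by root-finding on the
        Lagrange multiplier."""
        ssm = _toy_ssm(rng)
        expected = rng.standard_normal((30, 3))
        patient = expected + rng.standard_normal((30, 3)) * 3.0
        ne = closest_control(patient, ssm, expected)

        d = (patient - expected).ravel()
        c_star = ssm.modes @ d
        lam = ssm.mode_variances
        d2_crit = float(stats.chi2.ppf(0.95, ssm.n_modes))

        def d2_at(mu):
            c = c_star / (1.0 + mu)
            return float(np.sum(c**2 / lam)) - d2_crit

        if d2_at(0.0) <= 0:
            c_oracle = c_star
        else:
            mu = brentq(d2_at, 0.0, 1e6, xtol=1e-14, rtol=1e-15)
            c_oracle = c_star / (1.0 + mu)
        oracle_vertices = expected + ssm.reconstruct(c_oracle).reshape(30, 3)
        assert np.sqrt(np.mean((ne.vertices - oracle_vertices) ** 2)) < 1e-8

    def test_idempotence(self, rng):
        ssm = _toy_ssm(rng)
        expected = rng.standard_normal((30, 3))
        patient = expected + rng.standard_normal((30, 3)) * 2.5
        ne1 = normal_equivalent(patient, ssm, expected)
        ne2 = normal_equivalent(ne1.vertices, ssm, expected)
        assert np.sqrt(np.mean((ne2.vertices - ne1.vertices) ** 2)) < 1e-6

    def test_juvenile_face_pulled_toward_adult_mean(self, full_spec, full_model):
        """A young face assessed against an adult model is reconstructed
        closer to the adult expected face than the input was."""
        entry = full_model.entries[-1]  # oldest grid age
        juvenile = simulate_patient(full_spec, age=2.0, seed=4)
        aligned = align_to_expected(juvenile.vertices, entry.expected)
        ne = normal_equivalent(aligned, entry.ssm, entry.expected,
                               normals=entry.normals)
        rms_in = np.sqrt(np.mean((aligned - entry.expected) ** 2))
        rms_ne = np.sqrt(np.mean((ne.vertices - entry.expected) ** 2))
        assert rms_ne < rms_in
        assert ne.tail_probability >= 0.05 - 1e-9


class TestMorph:
    _base = None

    def _shape(self, rng, size=None, age=1.0, sid="s"):
        if TestMorph._base is None:
            TestMorph._base = np.random.default_rng(0).standard_normal((25, 3)) * 10
        v = TestMorph._base + rng.standard_normal((25, 3))
        if size is not None:
            v = v * (size / centroid_size(v))
        return CorrespondedShape(vertices=v, subject_id=sid, age=age)

    def test_identical_faces_average_to_the_face(self, rng):
        base = self._shape(rng, age=3.0)
        members = []
        for i in range(3):
            R, t = random_rigid(rng, max_angle=np.pi / 4)
            members.append(CorrespondedShape(
                vertices=base.vertices @ R + t, subject_id=f"m{i}", age=3.0))
        morph = make_morph(members)
        from facegrowth import procrustes_pair
        tr = procrustes_pair(morph.vertices, base.vertices)
        assert np.sqrt(np.mean((tr.apply(morph.vertices) - base.vertices) ** 2)) < 1e-7
        assert morph.size == pytest.approx(base.centroid_size)

    def test_morph_age_is_mean_member_age(self, rng):
        members = [self._shape(rng, age=a, sid=str(a)) for a in (2.5, 5.2, 0.4)]
        morph = make_morph(members)
        assert morph.age == pytest.approx(2.7)

    def test_morph_size_is_mean_member_size(self, rng):
        base = rng.standard_normal((25, 3))
        members = [
            CorrespondedShape(vertices=base * (s / centroid_size(base)),
                              subject_id=str(s), age=20.0)
            for s in (100.0, 120.0)
        ]
        morph = make_morph(members)
        assert abs(centroid_size(morph.vertices) - 110.0) < 1e-8
        assert morph.size == pytest.approx(110.0)


class TestSignatureExport:
    def test_zero_signature_exports_constant_zero(self, full_model, tmp_path):
        entry = full_model.entries[0]
        sig = facial_signature(entry.expected, full_model, age=entry.age)
        path = tmp_path / "sig.ply"
        export_signature_colormap(sig, full_model.topology, path)
        _, _, scalars = read_ply(path)
        assert np.abs(scalars["signature"]).max() < 1e-8

    def test_export_roundtrip_matches_signature(self, full_spec, full_model, tmp_path):
        field = bump_field(full_spec)
        patient = simulate_patient(full_spec, 30.0, dysmorphism_field=field,
                                   amplitude_in_sd=3.0, variation_scale=0.0)
        sig = facial_signature(patient, full_model)
        path = tmp_path / "bump.ply"
        export_signature_colormap(sig, full_model.topology, path)
        vertices, _, scalars = read_ply(path)
        np.testing.assert_array_equal(scalars["signature"], sig.z_normal)
        np.testing.assert_array_equal(vertices, sig.patient_vertices)
        # saturated scalars appear exactly where the injected bump is strong
        assert (np.abs(scalars["signature"]) > 2).any()
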