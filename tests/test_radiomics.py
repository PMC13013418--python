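"""Texture matrices, fractal dimension, filters and feature extraction."""

import numpy as np
import pytest

from nhocrad.imgvol import ScalarVolume, VolumeGeometry
from nhocrad.radiomics import (
    FeatureSpec,
    discretise_fixed_bin_count,
    extract_features,
    firstorder_features,
    fractal_dimension,
    glcm_features,
    glcm_features_from_matrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_features,
    glszm_zones,
    inverse_wavelet,
    log_filter,
    ngtdm_features,
    shape_features,
    wavelet_subbands,
)
from nhocrad.voi import VOISet

from conftest import make_mask, make_volume, sphere_mask_array


class TestGLCM:
    def test_worked_2x2_grid_contrast(self):
        # [[1,2],[1,2]] with symmetric co-occurrence at offset (0,1):
        # P(1,2)=P(2,1)=0.5 → contrast = Σ p (i−j)² = 1.0
        levels = np.array([[1, 2], [1, 2]]).reshape(2, 2, 1)
        p = glcm_matrix(levels, (0, 1, 0), 2)
        np.testing.assert_allclose(p, [[0, 0.5], [0.5, 0]])
        feats = glcm_features_from_matrix(p)
        assert feats["contrast"] == 1.0
        assert feats["energy"] == pytest.approx(0.5)
        assert feats["joint_entropy"] == pytest.approx(1.0)

    def test_hand_enumerated_pairs_on_3x3(self):
        levels = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]]).reshape(3, 3, 1)
        p = glcm_matrix(levels, (0, 1, 0), 3)
        # row pairs: (1,1),(1,2) / (1,2),(2,2) / (3,3),(3,3) → symmetric counts
        raw = np.array([[2, 2, 0], [2, 2, 0], [0, 0, 4]], float)
        np.testing.assert_allclose(p, raw / raw.sum())

    def test_constant_region_has_zero_contrast(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        feats = glcm_features(levels, 1)
        assert feats["contrast"] == 0.0
        assert feats["energy"] == pytest.approx(1.0)


class TestGLSZM:
    def test_worked_3x3_grid_zones(self):
        # three 26-connected zones of size 3 each → zone-size variance 0
        levels = np.array([[1, 1, 2], [1, 2, 2], [3, 3, 3]]).reshape(3, 3, 1)
        zones = glszm_zones(levels, 3)
        assert sorted(zones) == [(1, 3), (2, 3), (3, 3)]
        feats = glszm_features(levels, 3)
        assert feats["size_variance"] == 0.0

    def test_zone_split_raises_variance(self):
        levels = np.zeros((5, 1, 1), dtype=np.int64)
        levels[[0, 2, 3, 4], 0, 0] = 1  # zones of size 1 and 3
        feats = glszm_features(levels, 1)
        # p = 1/2 each at sizes 1, 3 → mean 2, variance 1
        assert feats["size_variance"] == pytest.approx(1.0)


class TestGLRLM:
    def test_simple_runs(self):
        levels = np.array([1, 1, 2, 2, 2, 1]).reshape(1, 6, 1)
        m = glrlm_matrix(levels, (0, 1, 0), 2)
        # level 1: runs of 2 and 1; level 2: one run of 3
        expected = np.zeros((2, 3))
        expected[0, 1] = 1
        expected[0, 0] = 1
        expected[1, 2] = 1
        np.testing.assert_array_equal(m, expected)

    def test_out_of_mask_breaks_runs(self):
        levels = np.array([1, 1, 0, 1, 1]).reshape(1, 5, 1)
        m = glrlm_matrix(levels, (0, 1, 0), 1)
        assert m[0, 1] == 2  # two runs of length 2


class TestNGTDM:
    def test_constant_region(self):
        levels = np.ones((4, 4, 4), dtype=np.int64)
        feats = ngtdm_features(levels, 1)
        assert feats["contrast"] == 0.0
        assert feats["coarseness"] > 1e10  # no grey-tone differences


class TestFractal:
    def test_filled_cube_dimension_three(self):
        est = fractal_dimension(np.ones((16, 16, 16), bool))
        assert est.fd == pytest.approx(3.0, abs=1e-6)
        assert est.counts == (16**3, 8**3, 4**3, 2**3)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_filled_plane_dimension_two(self):
        est = fractal_dimension(np.ones((16, 16, 1), bool))
        assert est.fd == pytest.approx(2.0, abs=1e-6)

    def test_single_voxel_dimension_zero(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert fractal_dimension(m).fd == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("axes", [(16, 1, 1), (16, 16, 1), (16, 16, 16), (32, 16, 1)])
    def test_interval_products_give_nonsingleton_axis_count(self, axes):
        est = fractal_dimension(np.ones(axes, bool))
        expected = sum(1 for a in axes if a > 1)
        assert est.fd == pytest.approx(expected, abs=0.1)

    def test_counts_non_increasing_and_empty_rejected(self):
        est = fractal_dimension(sphere_mask_array((20, 20, 20), (10, 10, 10), 7.0))
        assert all(a >= b for a, b in zip(est.counts, est.counts[1:]))
        with pytest.raises(ValueError, match="empty"):
            fractal_dimension(np.zeros((4, 4, 4), bool))


class TestWavelet:
    def test_constant_volume_highpass_bands_zero(self):
        vol = make_volume(np.full((8, 8, 8), 3.0))
        sb = wavelet_subbands(vol)
        for tag, band in sb.items():
            if "H" in tag:
                np.testing.assert_allclose(band.values, 0.0, atol=1e-10)

    def test_perfect_reconstruction(self, rng):
        vol = make_volume(rng.random((8, 8, 8)))
        rec = inverse_wavelet(wavelet_subbands(vol))
        np.testing.assert_allclose(rec, vol.values, atol=1e-8)

    def test_additive_ramp_kills_hhh(self):
        i, j, k = np.indices((8, 8, 8)).astype(float)
        vol = make_volume(2 * i + 3 * j + 0.5 * k)
        sb = wavelet_subbands(vol)
        np.testing.assert_allclose(sb["HHH"].values, 0.0, atol=1e-8)

    def test_short_axis_rejected_and_odd_axis_padded(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            wavelet_subbands(make_volume(np.ones((1, 8, 8))))
        sb = wavelet_subbands(make_volume(rng.random((7, 8, 9))))
        assert sb["LLL"].values.shape == (7, 8, 9)


class TestLoG:
    def test_constant_volume_zero_response(self):
        vol = make_volume(np.full((12, 12, 12), 4.0))
        np.testing.assert_allclose(log_filter(vol, 2.0).values, 0.0, atol=1e-10)

    def test_impulse_response_integrates_to_zero(self):
        vals = np.zeros((31, 31, 31))
        vals[15, 15, 15] = 1.0
        resp = log_filter(make_volume(vals), 2.0)
        assert abs(resp.values.sum()) < 1e-6

    def test_blob_response_peaks_near_blob_scale(self):
        # scale-normalised LoG at a Gaussian blob of scale σ*: |response| at the
        # centre is maximised at σ = σ*·√(2/3) in 3-D — an interior peak near σ*
        sigma_star = 3.0
        i, j, k = np.indices((41, 41, 41)).astype(float)
        d2 = (i - 20) ** 2 + (j - 20) ** 2 + (k - 20) ** 2
        vol = make_volume(np.exp(-d2 / (2 * sigma_star**2)))
        sweep = np.linspace(0.8, 6.0, 14)
        resp = [abs(log_filter(vol, s).values[20, 20, 20]) for s in sweep]
        best = sweep[int(np.argmax(resp))]
        assert best == pytest.approx(sigma_star * np.sqrt(2 / 3), abs=0.45)

    def test_sigma_in_physical_mm(self):
        # the response profile along z, at equal physical offsets, must agree
        # after normalisation regardless of z spacing
        vals = np.zeros((21, 21, 17))
        vals[10, 10, 8] = 1.0
        iso = log_filter(make_volume(vals), 3.0)
        aniso_vals = np.zeros((21, 21, 9))
        aniso_vals[10, 10, 4] = 1.0
        aniso = log_filter(make_volume(aniso_vals, spacing=(1, 1, 2)), 3.0)
        prof_iso = iso.values[10, 10, 8 + 4] / iso.values[10, 10, 8]  # z = +4 mm
        prof_aniso = aniso.values[10, 10, 4 + 2] / aniso.values[10, 10, 4]
        assert prof_aniso == pytest.approx(prof_iso, rel=0.05)


class TestDiscretise:
    def test_affine_rescaling_invariance(self, rng):
        x = rng.random(500) * 20
        a = discretise_fixed_bin_count(x, 32)
        b = discretise_fixed_bin_count(3.7 * x + 11.0, 32)
        np.testing.assert_array_equal(a, b)

    def test_constant_input_single_level(self):
        np.testing.assert_array_equal(
            discretise_fixed_bin_count(np.full(10, 5.0), 16), np.ones(10, np.int64)
        )


class TestFirstOrder:
    def test_constant_voi_zero_variance_and_entropy(self):
        v = np.full(50, 4.0)
        lv = discretise_fixed_bin_count(v, 16)
        f = firstorder_features(v, lv)
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["uniformity"] == 1.0


class TestShape:
    def test_sphere_volume_and_sphericity(self):
        mask = make_mask(sphere_mask_array((40, 40, 40), (20, 20, 20), 12.0))
        f = shape_features(mask)
        assert f["volume_mm3"] == pytest.approx(4 / 3 * np.pi * 12**3, rel=0.05)
        assert f["sphericity"] == pytest.approx(1.0, abs=0.08)
        assert f["max_diameter_mm"] == pytest.approx(24.0, abs=1.5)
        assert f["elongation"] == pytest.approx(1.0, abs=0.05)


@pytest.fixture(scope="module")
def voiset_and_pet():
    sphere = sphere_mask_array((48, 48, 48), (20, 24, 24), 9.0)
    rng = np.random.default_rng(7)
    vals = np.where(sphere, 8.0, 0.5) + rng.random((48, 48, 48))
    pet = make_volume(vals)
    lesion = make_mask(sphere, label="lesion")
    from nhocrad.voi import SegmentationParams, build_annuli

    annuli = build_annuli(lesion, SegmentationParams(shell_thickness_mm=6.0))
    return pet, VOISet(lesion=lesion, annuli=annuli, background=[])


class TestExtract:
    def test_names_and_finiteness(self, voiset_and_pet):
        pet, vs = voiset_and_pet
        spec = FeatureSpec(resample_spacing=None, log_sigmas_mm=(2.0,))
        vec = extract_features(pet, vs, spec, patient_id="p1")
        assert all(np.isfinite(v) for v in vec.values.values())
        name = "PET.lesion.original.glszm.size_variance"
        assert name in vec.values
        assert vec.provenance[name] == {
            "modality": "PET", "voi": "lesion", "family": "glszm",
            "transform": "original",
        }
        assert any(k.startswith("PET.annulus1.wavelet-HHL.") for k in vec.values)
        assert any(".log-2mm." in k for k in vec.values)

    def test_translation_invariance_of_texture(self, voiset_and_pet):
        pet, vs = voiset_and_pet
        spec = FeatureSpec(resample_spacing=None, wavelet=None, log_sigmas_mm=(),
                           families=("glcm", "glszm", "firstorder"),
                           include_fractal=False)
        vec0 = extract_features(pet, vs, spec)
        shift = 3
        pet2 = make_volume(np.roll(pet.values, shift, axis=0))
        vs2 = VOISet(
            lesion=make_mask(np.roll(vs.lesion.values, shift, axis=0), label="lesion"),
            annuli=[make_mask(np.roll(a.values, shift, axis=0), label=a.label)
                    for a in vs.annuli],
            background=[],
        )
        vec1 = extract_features(pet2, vs2, spec)
        for k in vec0.values:
            assert vec1.values[k] == pytest.approx(vec0.values[k], abs=1e-10), k

    def test_tiny_voi_yields_missing_not_zero(self):
        vals = np.full((12, 12, 12), 2.0)
        pet = make_volume(vals)
        m = np.zeros((12, 12, 12), bool)
        m[5, 5, 5] = True
        vs = VOISet(lesion=make_mask(m, label="lesion"))
        spec = FeatureSpec(resample_spacing=None)
        vec = extract_features(pet, vs, spec)
        assert np.isnan(vec.values["PET.lesion.original.firstorder.mean"])

    def test_manifest_round_trip(self, voiset_and_pet, tmp_path):
        import json

        pet, vs = voiset_and_pet
        spec = FeatureSpec(resample_spacing=None, wavelet=None, log_sigmas_mm=(),
                           families=("firstorder",), include_fractal=False)
        vec = extract_features(pet, vs, spec)
        vec.write_manifest(tmp_path / "m.json", spec)
        manifest = json.loads((tmp_path / "m.json").read_text())
        assert set(manifest["features"]) == set(vec.values)
        assert manifest["spec"]["families"] == ["firstorder"]
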