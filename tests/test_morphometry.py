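"""Surface-area and contact estimators against analytic and brute-force oracles."""

import math

import numpy as np
import pytest

from pacinia import morphometry
from pacinia.datatypes import LabeledVolume
from pacinia.morphometry import (
    ContactSummary,
    SliceContact,
    contact_area_from_overlap,
    contact_map,
    nucleus_contact_correlation,
    protrusion_contact_area,
    surface_area,
)
from pacinia.synthetic import PhantomSpec, make_corpuscle_phantom, make_cylinder_phantom


def _two_square_volume(gap_px: int, n_slices: int = 2, pitch_nm: float = 20.0):
    """Two 10x10 squares separated horizontally by ``gap_px`` background pixels."""
    plane = np.zeros((30, 40 + gap_px), dtype=np.uint16)
    plane[10:20, 5:15] = 1
    plane[10:20, 15 + gap_px:25 + gap_px] = 2
    labels = np.repeat(plane[None], n_slices, axis=0)
    return LabeledVolume(labels, (pitch_nm, pitch_nm, 100.0), {1: "axon", 2: "LSC"})


class TestSurfaceArea:
    def test_area_is_total_perimeter_times_dz(self):
        vol, _ = make_cylinder_phantom(1.0, 0.5, (20.0, 20.0, 100.0))
        est = surface_area(vol, 1)
        assert est.surface_area_um2 == pytest.approx(
            est.total_perimeter_um * vol.dz_um, rel=1e-12
        )
        assert est.total_perimeter_um == pytest.approx(
            est.per_slice_perimeter_um.sum(), rel=1e-12
        )

    def test_digitized_cylinder_matches_analytic_area(self):
        vol, truth = make_cylinder_phantom(1.0, 0.3, (20.0, 20.0, 100.0))
        est = surface_area(vol, 1)
        assert est.surface_area_um2 == pytest.approx(truth.surface_area_um2[1], rel=0.02)

    def test_error_decreases_with_finer_pitch(self):
        errs = []
        for pitch in (40.0, 20.0):
            vol, truth = make_cylinder_phantom(1.0, 0.2, (pitch, pitch, 100.0))
            est = surface_area(vol, 1).surface_area_um2
            errs.append(abs(est - truth.surface_area_um2[1]) / truth.surface_area_um2[1])
        assert errs[1] < errs[0]

    def test_unknown_label_raises(self):
        vol, _ = make_cylinder_phantom(1.0, 0.2, (20.0, 20.0, 100.0))
        with pytest.raises(KeyError):
            surface_area(vol, 99)

    def test_label_with_no_voxels_has_zero_area(self):
        labels = np.zeros((2, 10, 10), dtype=np.uint16)
        labels[:, 2:5, 2:5] = 1
        vol = LabeledVolume(labels, (20.0, 20.0, 100.0), {1: "axon", 2: "LSC"})
        assert surface_area(vol, 2).surface_area_um2 == 0.0

    def test_invariant_under_translation_and_rotation(self):
        vol, _ = make_cylinder_phantom(0.5, 0.2, (20.0, 20.0, 100.0))
        base = surface_area(vol, 1).surface_area_um2
        shifted = LabeledVolume(
            np.roll(vol.labels, (3, -2), axis=(1, 2)), vol.voxel_size_nm, vol.label_table
        )
        rotated = LabeledVolume(
            np.rot90(vol.labels, axes=(1, 2)).copy(), vol.voxel_size_nm, vol.label_table
        )
        assert surface_area(shifted, 1).surface_area_um2 == pytest.approx(base, rel=1e-9)
        assert surface_area(rotated, 1).surface_area_um2 == pytest.approx(base, rel=1e-9)


class TestContactMap:
    def test_distant_labels_have_empty_summary(self):
        vol = _two_square_volume(gap_px=10)  # 200 nm apart at 20 nm pitch
        summary = contact_map(vol, 1, 2, gap_nm=30.0)
        assert summary.n_slices_with_contact == 0
        assert summary.total_arc_um == 0.0
        assert summary.first_contact_z_um(vol.dz_um) is None

    def test_close_labels_register_contact(self):
        vol = _two_square_volume(gap_px=1)  # 20 nm apart
        summary = contact_map(vol, 1, 2, gap_nm=30.0)
        assert summary.n_slices_with_contact == vol.n_slices
        # facing 10-px edges, 0.2 um each: arc ~0.2 um per slice
        per_slice = summary.total_arc_um / vol.n_slices
        assert per_slice == pytest.approx(0.2, rel=0.35)
        assert summary.first_contact_z_um(vol.dz_um) == 0.0

    def test_quarter_arc_phantom_recovers_analytic_contact_area(self):
        spec = PhantomSpec(
            axon_radius_um=1.0, axon_length_um=0.5, n_shells=1,
            shell_thickness_um=0.3, shell_gap_nm=20.0, cleft_angle_deg=270.0,
            protrusion_count=0, voxel_size_nm=(20.0, 20.0, 100.0),
        )
        vol, truth = make_corpuscle_phantom(spec)
        summary = contact_map(vol, 1, 2, gap_nm=30.0)
        area = contact_area_from_overlap(summary, vol.dz_um)
        assert area == pytest.approx(truth.contact(1, 2).area_um2, rel=0.05)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(4)
        from scipy.ndimage import gaussian_filter

        for _ in range(5):
            f = gaussian_filter(rng.normal(size=(2, 40, 40)), (0, 3, 3))
            labels = np.zeros_like(f, dtype=np.uint16)
            labels[f > np.quantile(f, 0.8)] = 1
            labels[f < np.quantile(f, 0.2)] = 2
            vol = LabeledVolume(labels, (20.0, 20.0, 100.0), {1: "axon", 2: "LSC"})
            assert contact_map(vol, 1, 2, 60.0) == contact_map(vol, 2, 1, 60.0)

    def test_contact_area_bounded_by_surface_areas(self, corpuscle_default):
        vol, _ = corpuscle_default
        summary = contact_map(vol, 1, 2, gap_nm=30.0)
        area = contact_area_from_overlap(summary, vol.dz_um)
        smallest = min(
            surface_area(vol, 1).surface_area_um2, surface_area(vol, 2).surface_area_um2
        )
        assert 0 < area <= smallest

    def test_same_label_rejected(self):
        vol = _two_square_volume(gap_px=1)
        with pytest.raises(ValueError):
            contact_map(vol, 1, 1)

    def test_subpixel_gap_warns(self):
        vol = _two_square_volume(gap_px=1)
        with pytest.warns(UserWarning, match="pitch"):
            contact_map(vol, 1, 2, gap_nm=10.0)


class TestContactAreaFormula:
    def test_half_overlap_perimeter_times_dz(self):
        summary = ContactSummary(pair=(1, 2), gap_nm=30.0,
                                 slices=[SliceContact(0, 2.0, 4.0, 1)])
        assert contact_area_from_overlap(summary, 0.05) == pytest.approx(0.1)

    def test_empty_overlap_is_zero(self):
        summary = ContactSummary(pair=(1, 2), gap_nm=30.0)
        assert contact_area_from_overlap(summary, 0.05) == 0.0

    def test_negative_dz_rejected(self):
        summary = ContactSummary(pair=(1, 2), gap_nm=30.0)
        with pytest.raises(ValueError):
            contact_area_from_overlap(summary, -0.05)


class TestProtrusionContacts:
    def test_worked_example(self):
        assert protrusion_contact_area([0.2, 0.3]) == pytest.approx(0.05)

    def test_empty_list_is_zero(self):
        assert protrusion_contact_area([]) == 0.0

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(0)
        ranges = rng.uniform(0, 2.0, size=1000)
        brute = sum(float(r) * 0.1 for r in ranges)
        assert protrusion_contact_area(ranges) == pytest.approx(brute, rel=1e-12)

    def test_negative_range_rejected(self):
        with pytest.raises(ValueError):
            protrusion_contact_area([0.1, -0.2])


class TestNucleusContactCorrelation:
    def test_perfect_linear_relations(self):
        z = [1.0, 2.0, 3.0, 4.0]
        r, p = nucleus_contact_correlation(z, [2.0, 4.0, 6.0, 8.0])
        assert r == pytest.approx(1.0)
        r, _ = nucleus_contact_correlation(z, [8.0, 6.0, 4.0, 2.0])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r, _ = nucleus_contact_correlation(x, y)
        brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(brute, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            nucleus_contact_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            nucleus_contact_correlation([1.0, 2.0], [1.0, 2.0])
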