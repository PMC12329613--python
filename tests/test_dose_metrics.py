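"""Per-slice and per-exam dose-index computations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ssdelp.dose_metrics import (
    AAPM_BODY_COEFFICIENTS,
    AxialSlice,
    SliceDoseRecord,
    effective_diameter,
    exam_from_slices,
    exam_indices,
    mean_ssde,
    patient_contour_mask,
    remove_table,
    slice_ssde,
    ssde_conversion_factor,
    water_equivalent_diameter,
)

from conftest import ellipse_slice, uniform_slice, water_disc_slice

A, B = AAPM_BODY_COEFFICIENTS
DW_UNIT = math.log(A) / B  # diameter where the conversion factor crosses 1


class TestEffectiveDiameter:
    @pytest.mark.parametrize(
        "ap,lat,expected", [(30, 30, 30.0), (0, 45, 0.0), (20, 45, 30.0)]
    )
    def test_geometric_mean(self, ap, lat, expected):
        assert effective_diameter(ap, lat) == pytest.approx(expected)

    def test_negative_extent_rejected(self):
        with pytest.raises(ValueError):
            effective_diameter(-1.0, 30.0)


class TestWaterEquivalentDiameter:
    def test_uniform_water_area_equivalent(self):
        # all-water ROI: Dw reduces to the area-equivalent diameter
        slc = uniform_slice(0.0, shape=(20, 40),
                            spacing=math.sqrt(math.pi * 16**2 / 800))
        assert water_equivalent_diameter(slc) == pytest.approx(32.0, rel=1e-12)

    def test_air_contributes_nothing(self):
        slc = uniform_slice(-1000.0)
        assert water_equivalent_diameter(slc) == 0.0

    def test_ellipse_matches_closed_form(self):
        # water ellipse semi-axes 15 x 10 cm -> Dw = 2*sqrt(150)
        slc = ellipse_slice(10.0, 15.0, spacing=0.05)
        expected = 2.0 * math.sqrt(150.0)
        assert water_equivalent_diameter(slc) == pytest.approx(expected, rel=0.01)

    def test_roi_mask_restricts_area(self):
        slc = uniform_slice(0.0, shape=(10, 10), spacing=1.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        full = water_equivalent_diameter(slc)
        half = water_equivalent_diameter(slc, mask)
        assert half == pytest.approx(full / math.sqrt(2.0), rel=1e-12)

    def test_empty_or_misshapen_mask_rejected(self):
        slc = uniform_slice(0.0, shape=(8, 8))
        with pytest.raises(ValueError):
            water_equivalent_diameter(slc, np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            water_equivalent_diameter(slc, np.ones((4, 8), dtype=bool))

    def test_sub_air_roi_clamps_to_zero_with_warning(self):
        slc = uniform_slice(-1024.0)  # clamp floor is below pure air
        with pytest.warns(UserWarning):
            assert water_equivalent_diameter(slc) == 0.0


class TestConversionFactor:
    def test_unit_crossing(self):
        assert ssde_conversion_factor(DW_UNIT) == pytest.approx(1.0, rel=1e-12)

    def test_strictly_decreasing(self):
        assert ssde_conversion_factor(20.0) > ssde_conversion_factor(30.0)

    def test_published_form_at_25cm(self):
        assert ssde_conversion_factor(25.0) == pytest.approx(
            3.704369 * math.exp(-0.03671937 * 25.0), rel=1e-12
        )

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            ssde_conversion_factor(0.0)


class TestSliceSsde:
    def test_zero_ctdi_gives_zero_dose(self):
        rec = slice_ssde(water_disc_slice(30.0, ctdi=0.0))
        assert rec.ssde == 0.0

    def test_unit_conversion_diameter(self):
        # at the unit-crossing diameter SSDE equals CTDIvol
        rec = slice_ssde(water_disc_slice(DW_UNIT, ctdi=10.0))
        assert rec.ssde == pytest.approx(10.0, rel=1e-9)

    def test_ellipse_composition(self):
        slc = ellipse_slice(10.0, 15.0, spacing=0.05, ctdi=8.0)
        dw_true = 2.0 * math.sqrt(150.0)
        rec = slice_ssde(slc)
        assert rec.ssde == pytest.approx(
            8.0 * ssde_conversion_factor(dw_true), rel=0.01
        )
        assert rec.ssde == pytest.approx(rec.conversion_factor * 8.0, rel=1e-12)


class TestMeanSsde:
    def test_constant_and_two_point(self):
        recs = [SliceDoseRecord(z, 30.0, 1.2, 6.0) for z in range(5)]
        assert mean_ssde(recs) == pytest.approx(6.0)
        recs = [SliceDoseRecord(0, 30.0, 1.2, 4.0), SliceDoseRecord(1, 30.0, 1.2, 6.0)]
        assert mean_ssde(recs) == pytest.approx(5.0)

    def test_matches_running_sum_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.uniform(2.0, 20.0, 80)
        recs = [SliceDoseRecord(i * 0.5, 25.0, 1.4, v) for i, v in enumerate(vals)]
        acc = 0.0
        for v in vals:
            acc += v
        assert mean_ssde(recs) == pytest.approx(acc / 80, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_ssde([])


class TestExamIndices:
    def test_single_slice(self):
        rec = SliceDoseRecord(0.0, 30.0, 1.0, 10.0)
        idx = exam_indices([rec], slice_interval=0.5)
        assert idx.ssde_lp == pytest.approx(5.0)
        assert idx.scan_length == pytest.approx(0.5)

    def test_uniform_ctdi_dlp(self):
        f = 1.25
        recs = [SliceDoseRecord(i * 0.5, 28.0, f, f * 8.0) for i in range(80)]
        idx = exam_indices(recs, slice_interval=0.5)
        assert idx.scan_length == pytest.approx(40.0)
        assert idx.dlp == pytest.approx(320.0, rel=1e-12)

    def test_modulated_ctdi_matches_per_slice_sum(self):
        rng = np.random.default_rng(7)
        ctdi = rng.uniform(4.0, 25.0, 60)
        f = rng.uniform(1.0, 1.6, 60)
        recs = [
            SliceDoseRecord(i * 0.5, 28.0, fi, fi * ci)
            for i, (fi, ci) in enumerate(zip(f, ctdi))
        ]
        idx = exam_indices(recs, slice_interval=0.5)
        assert idx.dlp == pytest.approx(float(np.sum(ctdi)) * 0.5, rel=1e-9)
        assert idx.ssde_lp == pytest.approx(float(np.sum(f * ctdi)) * 0.5, rel=1e-9)

    def test_ssde_lp_to_dlp_ratio_bounded_by_conversion_factors(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(1.0, 1.8, 40)
        ctdi = rng.uniform(5.0, 20.0, 40)
        recs = [
            SliceDoseRecord(i * 0.5, 25.0, fi, fi * ci)
            for i, (fi, ci) in enumerate(zip(f, ctdi))
        ]
        idx = exam_indices(recs, slice_interval=0.5)
        ratio = idx.ssde_lp / idx.dlp
        assert f.min() - 1e-12 <= ratio <= f.max() + 1e-12

    def test_bad_inputs_rejected(self):
        rec = SliceDoseRecord(0.0, 30.0, 1.0, 10.0)
        with pytest.raises(ValueError):
            exam_indices([], 0.5)
        with pytest.raises(ValueError):
            exam_indices([rec], 0.0)
        out_of_order = [SliceDoseRecord(1.0, 30.0, 1.0, 10.0), rec]
        with pytest.raises(ValueError):
            exam_indices(out_of_order, 0.5)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

hu_grids = st.integers(4, 16).flatmap(
    lambda n: st.lists(
        st.lists(st.floats(-1000.0, 300.0), min_size=n, max_size=n),
        min_size=4,
        max_size=12,
    )
)


@given(grid=hu_grids, pad=st.integers(1, 6))
def test_air_padding_leaves_wed_unchanged(grid, pad):
    """Appending air pixels must not change the water-equivalent diameter."""
    px = np.array(grid)
    slc = AxialSlice(px, 0.8, 0.0, 10.0)
    padded = AxialSlice(
        np.pad(px, ((0, pad), (pad, 0)), constant_values=-1000.0), 0.8, 0.0, 10.0
    )
    d0 = water_equivalent_diameter(slc)
    d1 = water_equivalent_diameter(padded)
    assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-12)


@given(grid=hu_grids, scale=st.floats(0.1, 10.0))
def test_pixel_spacing_scale_equivariance(grid, scale):
    """Scaling the pixel spacing by s scales Dw by s."""
    px = np.array(grid)
    d0 = water_equivalent_diameter(AxialSlice(px, 1.0, 0.0, 10.0))
    d1 = water_equivalent_diameter(AxialSlice(px, scale, 0.0, 10.0))
    assert d1 == pytest.approx(scale * d0, rel=1e-9, abs=1e-12)


@given(st.floats(5.0, 55.0), st.floats(0.1, 10.0))
def test_conversion_factor_monotone_decreasing(dw, delta):
    assert ssde_conversion_factor(dw) > ssde_conversion_factor(dw + delta)


@given(st.lists(st.floats(0.1, 30.0), min_size=1, max_size=30))
def test_mean_ssde_bounded_by_extremes(vals):
    recs = [SliceDoseRecord(i * 0.5, 25.0, 1.3, v) for i, v in enumerate(vals)]
    m = mean_ssde(recs)
    assert min(vals) - 1e-9 <= m <= max(vals) + 1e-9


# ---------------------------------------------------------------------------
# segmentation helpers
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_contour_mask_selects_body(self):
        slc = ellipse_slice(6.0, 9.0, spacing=0.2)
        mask = patient_contour_mask(slc)
        expected_area = math.pi * 6.0 * 9.0
        assert mask.sum() * slc.pixel_area == pytest.approx(expected_area, rel=0.02)
        # contour ROI agrees with the full-FOV convention on clean images
        assert water_equivalent_diameter(slc, mask) == pytest.approx(
            water_equivalent_diameter(slc), rel=1e-9
        )

    def test_remove_table_drops_offcentre_component(self):
        slc = ellipse_slice(6.0, 9.0, spacing=0.2)
        px = slc.pixels.copy()
        px[-4:, :20] = 100.0  # table pad far from the centre
        with_table = AxialSlice(px, slc.pixel_spacing, 0.0, 10.0)
        cleaned = remove_table(with_table)
        assert water_equivalent_diameter(cleaned) == pytest.approx(
            water_equivalent_diameter(slc), rel=1e-9
        )
        # the patient component is untouched
        assert (cleaned.pixels > -500).sum() == (slc.pixels > -500).sum()


class TestDicomReader:
    def _write_ct(self, path, raw, spacing_mm=1.0, z_mm=12.5, ctdi=9.5):
        import pydicom
        from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
        from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(path), Dataset(), file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.Rows, ds.Columns = raw.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelSpacing = [spacing_mm, spacing_mm]
        ds.SliceLocation = z_mm
        ds.CTDIvol = ctdi
        ds.PixelData = raw.astype(np.uint16).tobytes()
        ds.save_as(str(path), enforce_file_format=True)

    def test_rescale_and_unit_mapping(self, tmp_path):
        from ssdelp.dose_metrics import read_dicom_slice

        raw = np.full((16, 16), 1024, dtype=np.uint16)  # water after rescale
        p = tmp_path / "slice.dcm"
        self._write_ct(p, raw, spacing_mm=2.0, z_mm=25.0, ctdi=7.5)
        slc = read_dicom_slice(p)
        assert slc.pixels.shape == (16, 16)
        assert float(slc.pixels[0, 0]) == 0.0
        assert slc.pixel_spacing == pytest.approx(0.2)  # mm -> cm
        assert slc.z_position == pytest.approx(2.5)
        assert slc.ctdi_vol == pytest.approx(7.5)

    def test_series_sorted_by_z(self, tmp_path):
        from ssdelp.dose_metrics import read_dicom_series

        raw = np.full((8, 8), 1024, dtype=np.uint16)
        paths = []
        for i, z in enumerate([20.0, 5.0, 12.5]):
            p = tmp_path / f"s{i}.dcm"
            self._write_ct(p, raw, z_mm=z)
            paths.append(p)
        series = read_dicom_series(paths)
        assert [s.z_position for s in series] == pytest.approx([0.5, 1.25, 2.0])


class TestExamFromSlices:
    def test_interval_inferred_from_z(self):
        slices = [water_disc_slice(28.0, z=i * 0.5, ctdi=9.0) for i in range(6)]
        recs, idx = exam_from_slices(slices)
        assert idx.n_slices == 6
        assert idx.scan_length == pytest.approx(3.0)

    def test_single_slice_needs_interval(self):
        with pytest.raises(ValueError):
            exam_from_slices([water_disc_slice(28.0)])

    def test_unknown_roi_rejected(self):
        with pytest.raises(ValueError):
            exam_from_slices([water_disc_slice(28.0)], 0.5, roi="patient")
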