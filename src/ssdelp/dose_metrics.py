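"""Per-slice and per-exam CT dose indices.

This module implements the size-specific dose estimate (SSDE) chain for a
stack of axial CT slices:

* **effective diameter** — the geometric-mean patient diameter
  ``sqrt(AP x LAT)`` from anteroposterior and lateral extents;
* **water-equivalent diameter** ``Dw`` — the diameter of the water cylinder
  with the same integrated attenuation as the imaged cross-section, computed
  from CT numbers (HU) inside a region of interest;
* the **size-specific conversion factor** ``f(Dw) = a*exp(-b*Dw)`` referenced
  to the 32 cm CTDI body phantom, so that ``SSDE(z) = f(Dw(z)) * CTDIvol(z)``;
* exam-level indices: scan length, dose-length product
  ``DLP = mean CTDIvol x L``, mean SSDE, and the SSDE-length product
  ``SSDE-LP = mean SSDE x L``.

Units are fixed project-wide: lengths in cm, doses in mGy, dose-length
products in mGy*cm.

The water-equivalent diameter is accumulated as ``sum over ROI of
(CT/1000 + 1) * pixel_area`` and then ``Dw = 2*sqrt(sum/pi)``.  This is
algebraically identical to the textbook mean-CT-times-area form, but air
pixels (-1000 HU) contribute exactly zero water-equivalent area, so the
default ROI can be the whole field of view (after table removal) without a
patient-contour segmentation step.  A contour-based ROI is available via
:func:`patient_contour_mask` for users who prefer that convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "AAPM_BODY_COEFFICIENTS",
    "HU_FLOOR",
    "AxialSlice",
    "SliceDoseRecord",
    "ExamIndices",
    "effective_diameter",
    "water_equivalent_diameter",
    "ssde_conversion_factor",
    "slice_ssde",
    "mean_ssde",
    "exam_indices",
    "exam_from_slices",
    "patient_contour_mask",
    "remove_table",
    "read_slice_table",
    "read_dicom_slice",
    "read_dicom_series",
]

#: Exponential fit coefficients (a, b) of the size-dependent conversion
#: factor f(Dw) = a*exp(-b*Dw) for the 32 cm reference phantom, the
#: abdominopelvic convention.  Override per call for a different table.
AAPM_BODY_COEFFICIENTS: tuple[float, float] = (3.704369, 0.03671937)

#: Clamped floor for CT numbers; values below are treated as air.
HU_FLOOR: float = -1024.0


@dataclass(frozen=True)
class AxialSlice:
    """One axial CT cross-section.

    Parameters
    ----------
    pixels
        2-D array of CT numbers (HU).  Values below :data:`HU_FLOOR` are
        clamped on construction.
    pixel_spacing
        Isotropic pixel edge length in cm (> 0).
    z_position
        Longitudinal table coordinate in cm.
    ctdi_vol
        Volume CT dose index reported for this slice in mGy (>= 0).
    """

    pixels: np.ndarray
    pixel_spacing: float
    z_position: float
    ctdi_vol: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixel grid must be a non-empty 2-D array")
        if not self.pixel_spacing > 0:
            raise ValueError(f"pixel_spacing must be > 0, got {self.pixel_spacing}")
        if self.ctdi_vol < 0:
            raise ValueError(f"ctdi_vol must be >= 0, got {self.ctdi_vol}")
        if px.min() < HU_FLOOR:  # clamp only when needed; skips a copy otherwise
            px = np.maximum(px, HU_FLOOR)
        object.__setattr__(self, "pixels", px)

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in cm^2."""
        return self.pixel_spacing ** 2


@dataclass(frozen=True)
class SliceDoseRecord:
    """Per-slice dose quantities: Dw, f(Dw) and SSDE at one z position."""

    z_position: float
    water_equivalent_diameter: float
    conversion_factor: float
    ssde: float

    def __post_init__(self) -> None:
        if self.water_equivalent_diameter < 0:
            raise ValueError("water_equivalent_diameter must be >= 0")
        if self.conversion_factor <= 0:
            raise ValueError("conversion_factor must be > 0")


@dataclass(frozen=True)
class ExamIndices:
    """Exam-level dose indices.

    ``n_slices`` is ``None`` for records reconstructed from cohort tables,
    where the slice count is not stored; it is always set when the indices
    are computed from a slice stack.
    """

    scan_length: float
    dlp: float
    mean_ssde: float
    ssde_lp: float
    n_slices: int | None = None

    def __post_init__(self) -> None:
        if not self.scan_length > 0:
            raise ValueError("scan_length must be > 0")
        if self.n_slices is not None and self.n_slices < 1:
            raise ValueError("n_slices must be >= 1 when given")
        expected = self.mean_ssde * self.scan_length
        if not math.isclose(self.ssde_lp, expected, rel_tol=1e-6, abs_tol=1e-9):
            raise ValueError(
                f"ssde_lp={self.ssde_lp} inconsistent with "
                f"mean_ssde*scan_length={expected}"
            )


def effective_diameter(ap_extent: float, lat_extent: float) -> float:
    """Geometric-mean patient diameter ``sqrt(AP x LAT)`` in cm.

    Parameters are the anteroposterior and lateral extents of the patient
    cross-section in cm; both must be non-negative.
    """
    if ap_extent < 0 or lat_extent < 0:
        raise ValueError(
            f"extents must be >= 0, got AP={ap_extent}, LAT={lat_extent}"
        )
    return math.sqrt(ap_extent * lat_extent)


def water_equivalent_diameter(
    slc: AxialSlice, roi_mask: np.ndarray | None = None
) -> float:
    """Water-equivalent diameter (cm) of one axial slice.

    Accumulates the water-equivalent area ``sum((CT/1000 + 1) * pixel_area)``
    over the ROI and returns ``2*sqrt(area_w/pi)``.  With ``roi_mask=None``
    the ROI is the full pixel grid; air pixels contribute zero, so a full
    field of view (with the table removed) and a tight patient contour give
    the same result up to noise in the background.

    A pathological ROI with negative total water-equivalent area (mean CT
    below -1000 HU is impossible for clamped input, but masks combined with
    degenerate data could produce it) yields 0.0 with a warning rather than
    raising, so batch runs do not abort.
    """
    px = slc.pixels
    if roi_mask is None:
        vals = px.ravel()
    else:
        mask = np.asarray(roi_mask, dtype=bool)
        if mask.shape != px.shape:
            raise ValueError(
                f"roi_mask shape {mask.shape} != pixel grid shape {px.shape}"
            )
        if not mask.any():
            raise ValueError("ROI mask selects no pixels")
        vals = px[mask]
    # sum(CT/1000 + 1) accumulated without an intermediate array
    area_w = (float(np.sum(vals)) / 1000.0 + vals.size) * slc.pixel_area
    if area_w < 0:
        warnings.warn(
            "negative water-equivalent area; clamping Dw to 0", stacklevel=2
        )
        return 0.0
    return 2.0 * math.sqrt(area_w / math.pi)


def ssde_conversion_factor(
    dw: float, coefficients: tuple[float, float] = AAPM_BODY_COEFFICIENTS
) -> float:
    """Size-dependent conversion factor ``f(Dw) = a*exp(-b*Dw)``.

    Strictly decreasing in ``dw``; crosses 1 at ``dw = ln(a)/b`` (about
    35.7 cm for the default body-phantom coefficients).
    """
    if not dw > 0:
        raise ValueError(f"dw must be > 0, got {dw}")
    a, b = coefficients
    return a * math.exp(-b * dw)


def slice_ssde(
    slc: AxialSlice,
    roi_mask: np.ndarray | None = None,
    coefficients: tuple[float, float] = AAPM_BODY_COEFFICIENTS,
) -> SliceDoseRecord:
    """Compute ``SSDE(z) = f(Dw(z)) * CTDIvol(z)`` for one slice."""
    dw = water_equivalent_diameter(slc, roi_mask)
    if dw <= 0:
        raise ValueError(
            f"non-positive water-equivalent diameter ({dw}) at "
            f"z={slc.z_position}; cannot form a conversion factor"
        )
    f = ssde_conversion_factor(dw, coefficients)
    return SliceDoseRecord(
        z_position=slc.z_position,
        water_equivalent_diameter=dw,
        conversion_factor=f,
        ssde=f * slc.ctdi_vol,
    )


def mean_ssde(records: Sequence[SliceDoseRecord]) -> float:
    """Arithmetic mean of per-slice SSDE over the scan range (mGy)."""
    if len(records) == 0:
        raise ValueError("mean_ssde requires at least one slice record")
    return float(np.mean([r.ssde for r in records]))


def exam_indices(
    records: Sequence[SliceDoseRecord], slice_interval: float
) -> ExamIndices:
    """Exam-level indices from ordered per-slice dose records.

    ``scan_length = n_slices * slice_interval`` (the imaged length;
    helical over-ranging is not modelled).  The per-slice CTDIvol is
    recovered as ``ssde / f``, so ``DLP = mean CTDIvol x scan length`` and
    ``SSDE-LP = mean SSDE x scan length`` come from the same records.
    """
    if len(records) == 0:
        raise ValueError("exam_indices requires at least one slice record")
    if not slice_interval > 0:
        raise ValueError(f"slice_interval must be > 0, got {slice_interval}")
    z = np.array([r.z_position for r in records])
    if np.any(np.diff(z) < 0):
        raise ValueError("slice records must be ordered by z_position")
    length = len(records) * slice_interval
    ssde_vals = np.array([r.ssde for r in records])
    ctdi_vals = ssde_vals / np.array([r.conversion_factor for r in records])
    m_ssde = float(ssde_vals.mean())
    return ExamIndices(
        scan_length=length,
        dlp=float(ctdi_vals.mean()) * length,
        mean_ssde=m_ssde,
        ssde_lp=m_ssde * length,
        n_slices=len(records),
    )


def exam_from_slices(
    slices: Sequence[AxialSlice],
    slice_interval: float | None = None,
    roi: str = "full",
    mask_table: bool = False,
    coefficients: tuple[float, float] = AAPM_BODY_COEFFICIENTS,
) -> tuple[list[SliceDoseRecord], ExamIndices]:
    """Run the full per-slice pipeline over a stack of axial slices.

    Parameters
    ----------
    slices
        Axial slices ordered by z position.
    slice_interval
        Longitudinal spacing in cm; inferred from the median z increment
        when omitted (requires >= 2 slices).
    roi
        ``"full"`` (whole grid; air contributes zero) or ``"contour"``
        (largest connected body region, holes filled).
    mask_table
        Remove off-centre high-attenuation components (patient table)
        before the ROI step.  Synthetic images carry no table and skip this.
    """
    if len(slices) == 0:
        raise ValueError("exam_from_slices requires at least one slice")
    if roi not in ("full", "contour"):
        raise ValueError(f"unknown roi convention {roi!r}")
    if slice_interval is None:
        if len(slices) < 2:
            raise ValueError("slice_interval required for a single slice")
        zs = np.array([s.z_position for s in slices])
        slice_interval = float(np.median(np.diff(zs)))
    records = []
    for slc in slices:
        if mask_table:
            slc = remove_table(slc)
        mask = patient_contour_mask(slc) if roi == "contour" else None
        records.append(slice_ssde(slc, mask, coefficients))
    return records, exam_indices(records, slice_interval)


def patient_contour_mask(
    slc: AxialSlice, hu_threshold: float = -500.0
) -> np.ndarray:
    """Binary mask of the patient body contour.

    Thresholds at ``hu_threshold``, keeps the largest connected component
    and fills interior holes (lung/bowel gas stays inside the contour).
    """
    fg = slc.pixels > hu_threshold
    if not fg.any():
        raise ValueError("no pixels above the contour threshold")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        fg = labels == keep
    return ndimage.binary_fill_holes(fg)


def remove_table(
    slc: AxialSlice, hu_threshold: float = -800.0, centre_fraction: float = 0.25
) -> AxialSlice:
    """Mask the patient table out of a real axial image.

    Connected components above ``hu_threshold`` that do not intersect the
    central region of the grid (a window of ``centre_fraction`` of each
    dimension) are replaced by air (-1000 HU).  Synthetic phantom slices
    contain no table, so this is a no-op for them.
    """
    fg = slc.pixels > hu_threshold
    labels, n = ndimage.label(fg)
    if n == 0:
        return slc
    ny, nx = slc.pixels.shape
    hy = max(1, int(ny * centre_fraction / 2))
    hx = max(1, int(nx * centre_fraction / 2))
    centre = labels[ny // 2 - hy : ny // 2 + hy + 1, nx // 2 - hx : nx // 2 + hx + 1]
    central_labels = set(np.unique(centre)) - {0}
    drop = ~np.isin(labels, sorted(central_labels)) & fg
    if not drop.any():
        return slc
    px = slc.pixels.copy()
    px[drop] = -1000.0
    return AxialSlice(px, slc.pixel_spacing, slc.z_position, slc.ctdi_vol)


# ---------------------------------------------------------------------------
# external inputs: slice tables, pixel stacks, minimal DICOM
# ---------------------------------------------------------------------------

def read_slice_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited per-slice table (exam_id, z, ctdi_vol).

    Comma-separated, one row per slice; returns the frame sorted by
    (exam_id, z).
    """
    df = pd.read_csv(path, dtype={"exam_id": str})
    required = {"exam_id", "z", "ctdi_vol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"slice table missing columns: {sorted(missing)}")
    return df.sort_values(["exam_id", "z"], kind="stable").reset_index(drop=True)


def read_dicom_slice(path: str | Path):
    """Minimal DICOM reader for one axial CT slice.

    Maps RescaleSlope/RescaleIntercept to HU, PixelSpacing and
    SliceLocation from mm to cm, and reads per-slice CTDIvol
    (0018,9345) when present (0.0 otherwise).  Requires isotropic pixels.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(float) * slope + intercept
    sy, sx = (float(v) for v in ds.PixelSpacing)
    if not math.isclose(sy, sx, rel_tol=1e-6):
        raise ValueError(f"anisotropic pixel spacing {sy} x {sx} mm unsupported")
    z_mm = float(getattr(ds, "SliceLocation", 0.0))
    ctdi = float(getattr(ds, "CTDIvol", 0.0))
    return AxialSlice(hu, pixel_spacing=sx / 10.0, z_position=z_mm / 10.0, ctdi_vol=ctdi)


def read_dicom_series(paths: Iterable[str | Path]) -> list[AxialSlice]:
    """Read several DICOM slices and return them ordered by z position."""
    slices = [read_dicom_slice(p) for p in paths]
    return sorted(slices, key=lambda s: s.z_position)
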