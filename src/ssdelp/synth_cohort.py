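"""Virtual abdominopelvic CT cohort generator.

Emulates the inputs of a conversion-factor study end-to-end, so calibration
and held-out validation can run with no external data:

* two cohorts (calibration / validation) with sex-specific sample counts
  and age distributions;
* per-exam body size as a longitudinal water-equivalent-diameter profile
  ``Dw(z)`` — a smooth parabolic taper around a sex-specific central
  diameter (the abdomen is widest mid-scan);
* tube-current modulation: automatic exposure control at a fixed image-noise
  target compensates attenuation roughly exponentially in water-equivalent
  thickness, so ``CTDIvol(z) = ctdi_ref * exp((Dw(z) - dw_ref)/efold)``;
* per-slice SSDE via the same conversion-factor curve the analysis uses,
  giving exam-true DLP, mean SSDE and SSDE-LP;
* a surrogate reference effective dose that is linear in the true SSDE-LP,
  ``E = k_sex * SSDE-LP * (1 + eps) * (1 + beta*(mean Dw - dw_ref))`` with
  multiplicative noise ``eps ~ N(0, sigma)``.  Linearity in SSDE-LP makes
  the true coefficient known exactly, so parameter recovery is testable;
  because DLP lacks the size correction, the DLP-to-dose relation has a
  size-dependent slope ``k_sex * f(Dw)`` by construction — large patients
  fan out on the DLP axis but not on the SSDE-LP axis.

Each exam can optionally be rasterized into a stack of axial slices (a
water-density ellipse of matching area on an air background), closing the
loop with :mod:`ssdelp.dose_metrics`: recomputing Dw and SSDE-LP from the
pixel stacks reproduces the generating values up to discretization.
Cohort-level generation uses the analytic profiles directly, since the
indices are exact functionals of ``Dw(z)``; rendering is reserved for
round-trip checks and image-pipeline demos.

Everything is driven by one integer seed through ``numpy`` Generators with
a fixed draw order, so a fixed seed gives byte-identical serialized
cohorts on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .cohort import Cohort, ExamRecord, SEXES
from .dose_metrics import (
    AAPM_BODY_COEFFICIENTS,
    AxialSlice,
    ExamIndices,
)

__all__ = [
    "GeneratorConfig",
    "VirtualExam",
    "generate_exam",
    "generate_cohorts",
    "rasterize_slice",
]

#: Scanner protocol carried as provenance metadata only (a helical
#: abdominopelvic adult protocol); it does not enter the dose arithmetic.
DEFAULT_PROTOCOL = {
    "scan_type": "helical",
    "tube_voltage_kv": 120,
    "volume_ec": "on (xyz tube-current modulation)",
    "rotation_time_ms": 500,
    "pitch_factor": 0.813,
    "single_collimation_mm": 0.5,
    "detector_rows": 80,
    "total_collimation_mm": 40,
    "noise_setting_sd": 15,
}


@dataclass
class GeneratorConfig:
    """All knobs of the virtual cohort, with study-shaped defaults.

    Lengths in cm, doses in mGy, effective dose in mSv, conversion
    coefficients in mSv/(mGy*cm).
    """

    # cohort sizes per (role, sex)
    n_calibration_male: int = 224
    n_calibration_female: int = 153
    n_validation_male: int = 159
    n_validation_female: int = 134

    # age distributions (years), clipped to the adult range
    age_mean_male: float = 63.0
    age_sd_male: float = 18.0
    age_mean_female: float = 60.0
    age_sd_female: float = 21.0
    age_min: float = 18.0
    age_max: float = 99.0

    # body size: central water-equivalent diameter (cm) and taper;
    # the per-sex normal is truncated at +/- dw_trunc_k SD (and globally at
    # [dw_min, dw_max]) — the scanner's adult abdominal patient range
    dw_mean_male: float = 26.5
    dw_mean_female: float = 24.5
    dw_sd: float = 4.0
    dw_trunc_k: float = 2.2
    dw_min: float = 15.0
    dw_max: float = 38.0
    dw_taper: float = 0.08  # fractional narrowing at the scan ends
    ap_lat_ratio: float = 0.75  # AP/LAT extent ratio of the ellipse

    # scan geometry (cm)
    scan_length_mean: float = 45.0
    scan_length_sd: float = 8.0
    scan_length_min: float = 30.0
    scan_length_max: float = 60.0
    slice_interval: float = 0.5

    # rasterization
    grid_size: int = 512
    pixel_spacing: float = 0.1
    tissue_noise_hu: float = 0.0

    # automatic exposure control:
    # CTDIvol = ctdi_ref * exp((Dw-dw_ref)/efold) * exp(eta), where eta ~
    # Uniform(-aec_log_halfwidth, +aec_log_halfwidth) is a per-exam output
    # offset (centering, arm position, phase-to-phase mA variation)
    aec_ctdi_ref: float = 10.0
    aec_dw_ref: float = 27.0
    aec_efold: float = 4.5
    aec_log_halfwidth: float = 0.5
    ctdi_min: float = 1.0
    ctdi_max: float = 80.0

    # surrogate reference-dose model
    k_male: float = 0.012
    k_female: float = 0.014
    noise_sd: float = 0.05
    size_bias_beta: float = 0.0  # extra per-cm size bias on the dose
    bias_dw_ref: float = 27.0

    # exclusion-flag prevalences (annotations only; no image artefacts)
    p_excluded_arm: float = 0.0
    p_excluded_metal: float = 0.0

    protocol: dict = field(default_factory=lambda: dict(DEFAULT_PROTOCOL))
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_calibration_male,
            self.n_calibration_female,
            self.n_validation_male,
            self.n_validation_female,
        )
        if any(c < 0 for c in counts):
            raise ValueError("cohort counts must be >= 0")
        for name in ("age_sd_male", "age_sd_female", "dw_sd", "dw_trunc_k",
                     "scan_length_sd", "noise_sd", "aec_log_halfwidth",
                     "tissue_noise_hu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_male <= 0 or self.k_female <= 0:
            raise ValueError("dose-model coefficients k must be > 0")
        if self.dw_mean_male <= 0 or self.dw_mean_female <= 0 or self.dw_min <= 0:
            raise ValueError("water-equivalent diameters must be > 0")
        if not 0 <= self.dw_taper < 1:
            raise ValueError("dw_taper must lie in [0, 1)")
        if self.slice_interval <= 0 or self.pixel_spacing <= 0:
            raise ValueError("slice_interval and pixel_spacing must be > 0")
        if self.grid_size < 8:
            raise ValueError("grid_size too small to hold a patient section")
        if self.scan_length_min <= 0:
            raise ValueError("scan lengths must be > 0")
        fov = self.grid_size * self.pixel_spacing
        lat_diam = self.dw_max / np.sqrt(self.ap_lat_ratio)
        if lat_diam > fov:
            raise ValueError(
                f"largest lateral extent {lat_diam:.1f} cm exceeds the "
                f"{fov:.1f} cm field of view; shrink dw_max or enlarge the grid"
            )

    def to_yaml(self, path: str | Path) -> None:
        doc = {"schema_version": 1, **asdict(self)}
        Path(path).write_text(
            yaml.safe_dump(doc, sort_keys=True, default_flow_style=False),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        doc.pop("schema_version", None)
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass(frozen=True)
class VirtualExam:
    """One generated exam: the exam record plus its generating profiles.

    ``slices`` is populated only when the exam was rasterized.
    """

    record: ExamRecord
    z: np.ndarray
    dw_profile: np.ndarray
    ctdi_profile: np.ndarray
    ssde_profile: np.ndarray
    slices: tuple[AxialSlice, ...] | None = None


def rasterize_slice(
    dw: float,
    grid_size: int,
    pixel_spacing: float,
    ap_lat_ratio: float = 0.75,
    tissue_noise_hu: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Rasterize a water-density ellipse of water-equivalent diameter ``dw``.

    The ellipse has area ``pi*(dw/2)^2`` (interior 0 HU) on an air
    background (-1000 HU), with AP (rows) to LAT (columns) extent ratio
    ``ap_lat_ratio``; pixel centres sample the ideal ellipse.
    """
    half = (grid_size - 1) / 2.0
    coords = (np.arange(grid_size) - half) * pixel_spacing
    semi_ap = 0.5 * dw * np.sqrt(ap_lat_ratio)
    semi_lat = 0.5 * dw / np.sqrt(ap_lat_ratio)
    yy = (coords / semi_ap) ** 2
    xx = (coords / semi_lat) ** 2
    inside = (yy[:, None] + xx[None, :]) <= 1.0
    pixels = np.full((grid_size, grid_size), -1000.0)
    pixels[inside] = 0.0
    if tissue_noise_hu > 0:
        if rng is None:
            raise ValueError("tissue noise requires an rng")
        pixels = pixels + inside * rng.normal(0.0, tissue_noise_hu, pixels.shape)
    return pixels


def generate_exam(
    config: GeneratorConfig,
    sex: str,
    rng: np.random.Generator,
    exam_id: str,
    render_pixels: bool = False,
) -> VirtualExam:
    """Draw one virtual exam for the given sex.

    The random draw order (age, scan length, central Dw, dose noise,
    exclusion flags) is fixed and independent of ``render_pixels``, so
    rendered and analytic runs of the same stream produce the same exams.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    c = config
    if sex == "male":
        age_mu, age_sd, dw_mu, k = c.age_mean_male, c.age_sd_male, c.dw_mean_male, c.k_male
    else:
        age_mu, age_sd, dw_mu, k = (
            c.age_mean_female, c.age_sd_female, c.dw_mean_female, c.k_female,
        )

    age = float(np.clip(np.round(rng.normal(age_mu, age_sd)), c.age_min, c.age_max))
    length_draw = float(
        np.clip(rng.normal(c.scan_length_mean, c.scan_length_sd),
                c.scan_length_min, c.scan_length_max)
    )
    dw_lo = max(c.dw_min, dw_mu - c.dw_trunc_k * c.dw_sd)
    dw_hi = min(c.dw_max, dw_mu + c.dw_trunc_k * c.dw_sd)
    dw_centre = float(np.clip(rng.normal(dw_mu, c.dw_sd), dw_lo, dw_hi))
    aec_offset = float(
        np.exp(rng.uniform(-c.aec_log_halfwidth, c.aec_log_halfwidth))
    )
    eps = float(rng.normal(0.0, c.noise_sd)) if c.noise_sd > 0 else 0.0
    flag_arm = bool(rng.random() < c.p_excluded_arm)
    flag_metal = bool(rng.random() < c.p_excluded_metal)

    n_slices = max(1, int(round(length_draw / c.slice_interval)))
    scan_length = n_slices * c.slice_interval
    z = np.arange(n_slices) * c.slice_interval
    u = np.linspace(-1.0, 1.0, n_slices) if n_slices > 1 else np.zeros(1)
    dw_profile = dw_centre * (1.0 - c.dw_taper * u**2)
    dw_profile = np.clip(dw_profile, c.dw_min, c.dw_max)

    ctdi_profile = np.clip(
        c.aec_ctdi_ref * aec_offset * np.exp((dw_profile - c.aec_dw_ref) / c.aec_efold),
        c.ctdi_min, c.ctdi_max,
    )
    a, b = AAPM_BODY_COEFFICIENTS
    f_profile = a * np.exp(-b * dw_profile)
    ssde_profile = f_profile * ctdi_profile

    m_ssde = float(ssde_profile.mean())
    indices = ExamIndices(
        scan_length=scan_length,
        dlp=float(ctdi_profile.mean()) * scan_length,
        mean_ssde=m_ssde,
        ssde_lp=m_ssde * scan_length,
        n_slices=n_slices,
    )
    size_bias = 1.0 + c.size_bias_beta * (float(dw_profile.mean()) - c.bias_dw_ref)
    effective_dose = k * indices.ssde_lp * (1.0 + eps) * size_bias

    record = ExamRecord(
        exam_id=exam_id,
        sex=sex,
        age=age,
        indices=indices,
        reference_effective_dose=effective_dose,
        excluded_arm_position=flag_arm,
        excluded_metal_implant=flag_metal,
    )

    slices = None
    if render_pixels:
        slices = tuple(
            AxialSlice(
                rasterize_slice(
                    float(dw_profile[i]), c.grid_size, c.pixel_spacing,
                    c.ap_lat_ratio, c.tissue_noise_hu,
                    rng if c.tissue_noise_hu > 0 else None,
                ),
                pixel_spacing=c.pixel_spacing,
                z_position=float(z[i]),
                ctdi_vol=float(ctdi_profile[i]),
            )
            for i in range(n_slices)
        )
    return VirtualExam(
        record=record,
        z=z,
        dw_profile=dw_profile,
        ctdi_profile=ctdi_profile,
        ssde_profile=ssde_profile,
        slices=slices,
    )


def generate_cohorts(config: GeneratorConfig) -> dict[str, Cohort]:
    """Generate the calibration and validation cohorts of the configuration.

    Returns ``{"calibration": Cohort, "validation": Cohort}`` with
    configured per-sex counts, deterministic under the config seed.
    Exam indices come from the analytic ``Dw(z)`` profiles; use
    :func:`generate_exam` with ``render_pixels=True`` for pixel stacks.
    """
    counts = {
        ("calibration", "male"): config.n_calibration_male,
        ("calibration", "female"): config.n_calibration_female,
        ("validation", "male"): config.n_validation_male,
        ("validation", "female"): config.n_validation_female,
    }
    if sum(counts.values()) == 0:
        raise ValueError("all cohort counts are zero")
    rng = np.random.default_rng(config.seed)
    out: dict[str, Cohort] = {}
    for role in ("calibration", "validation"):
        records = []
        for sex in SEXES:
            for i in range(counts[(role, sex)]):
                exam_id = f"{role[:3]}-{sex[0]}-{i + 1:04d}"
                records.append(generate_exam(config, sex, rng, exam_id).record)
        out[role] = Cohort(records=tuple(records), role=role, label="synthetic")
    return out
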