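import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ssdelp.cohort import Cohort, ExamRecord
from ssdelp.dose_metrics import AxialSlice, ExamIndices

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def uniform_slice(value_hu, shape=(20, 40), spacing=1.0, z=0.0, ctdi=10.0):
    """A slice whose pixels all hold one CT number."""
    return AxialSlice(np.full(shape, float(value_hu)), spacing, z, ctdi)


def water_disc_slice(dw, n=64, z=0.0, ctdi=10.0):
    """A full-grid water 'disc': uniform 0 HU with spacing chosen so the
    water-equivalent diameter is exactly ``dw``."""
    spacing = (dw / 2.0) * math.sqrt(math.pi / (n * n))
    return AxialSlice(np.zeros((n, n)), spacing, z, ctdi)


def ellipse_slice(semi_ap, semi_lat, spacing=0.05, margin=1.5, z=0.0, ctdi=8.0):
    """Water ellipse (0 HU) on air (-1000 HU), pixel centres sampled."""
    ny = int(2 * semi_ap * margin / spacing) | 1
    nx = int(2 * semi_lat * margin / spacing) | 1
    y = (np.arange(ny) - (ny - 1) / 2) * spacing
    x = (np.arange(nx) - (nx - 1) / 2) * spacing
    inside = (y[:, None] / semi_ap) ** 2 + (x[None, :] / semi_lat) ** 2 <= 1.0
    px = np.full((ny, nx), -1000.0)
    px[inside] = 0.0
    return AxialSlice(px, spacing, z, ctdi)


def make_record(
    exam_id,
    sex="male",
    age=60.0,
    scan_length=40.0,
    dlp=400.0,
    mean_ssde=13.0,
    dose=6.0,
    arm=False,
    metal=False,
):
    idx = ExamIndices(
        scan_length=scan_length,
        dlp=dlp,
        mean_ssde=mean_ssde,
        ssde_lp=mean_ssde * scan_length,
        n_slices=None,
    )
    return ExamRecord(
        exam_id=exam_id,
        sex=sex,
        age=age,
        indices=idx,
        reference_effective_dose=dose,
        excluded_arm_position=arm,
        excluded_metal_implant=metal,
    )


def make_cohort(records, role="calibration", label="toy"):
    return Cohort(records=tuple(records), role=role, label=label)


@pytest.fixture
def toy_cohort():
    """Six usable records (4 male, 2 female) plus flagged/non-positive ones."""
    recs = [
        make_record("m1", "male", dlp=300.0, mean_ssde=10.0, dose=4.8),
        make_record("m2", "male", dlp=400.0, mean_ssde=13.0, dose=6.3),
        make_record("m3", "male", dlp=500.0, mean_ssde=16.0, dose=7.7),
        make_record("m4", "male", dlp=600.0, mean_ssde=19.0, dose=9.2),
        make_record("f1", "female", dlp=350.0, mean_ssde=12.0, dose=6.7),
        make_record("f2", "female", dlp=450.0, mean_ssde=15.0, dose=8.4),
    ]
    return make_cohort(recs)
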