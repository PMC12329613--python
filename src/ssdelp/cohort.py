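"""Exam-level cohort model, exclusion filtering and delimited-table I/O.

A :class:`Cohort` is a set of :class:`ExamRecord` with a role tag
(``calibration`` — used to fit conversion coefficients — or ``validation``
— held out to verify them).  Records carry pre-annotated exclusion flags
(arm position in the scan field, metal implants) because both inflate the
apparent water-equivalent diameter; exclusion is by inspection, not
image-derived detection.  Filtering also drops records whose reference
effective dose is not positive, since only positive reference estimates
enter calibration and verification.

The on-disk format is a UTF-8 comma-separated table with a fixed header;
the writer always formats floats with ``%.10g`` so write -> read -> write
is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .dose_metrics import ExamIndices

__all__ = [
    "SEXES",
    "STRATA",
    "ROLES",
    "ExamRecord",
    "Cohort",
    "ExclusionReport",
    "filter_cohort",
    "stratify",
    "summarize",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

SEXES = ("male", "female")
STRATA = ("male", "female", "both")
ROLES = ("calibration", "validation")

#: Column order of the cohort table on disk.
COHORT_COLUMNS = [
    "exam_id",
    "sex",
    "age",
    "scan_length_cm",
    "dlp_mgycm",
    "mean_ssde_mgy",
    "ssde_lp_mgycm",
    "effective_dose_msv",
    "excl_arm",
    "excl_metal",
]


@dataclass(frozen=True)
class ExamRecord:
    """One patient exam with its dose indices and reference effective dose."""

    exam_id: str
    sex: str
    age: float
    indices: ExamIndices
    reference_effective_dose: float
    excluded_arm_position: bool = False
    excluded_metal_implant: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex label {self.sex!r} (expected one of {SEXES})")

    @property
    def usable(self) -> bool:
        """True if the record survives exclusion filtering."""
        return (
            not self.excluded_arm_position
            and not self.excluded_metal_implant
            and self.reference_effective_dose > 0
        )


@dataclass(frozen=True)
class Cohort:
    """A set of exam records with a role tag and free-text provenance label."""

    records: tuple[ExamRecord, ...]
    role: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown cohort role {self.role!r}")
        recs = tuple(self.records)
        ids = [r.exam_id for r in recs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate exam ids in cohort: {dupes[:5]}")
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ExamRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one row per exam (the on-disk column set)."""
        rows = [
            {
                "exam_id": r.exam_id,
                "sex": r.sex,
                "age": r.age,
                "scan_length_cm": r.indices.scan_length,
                "dlp_mgycm": r.indices.dlp,
                "mean_ssde_mgy": r.indices.mean_ssde,
                "ssde_lp_mgycm": r.indices.ssde_lp,
                "effective_dose_msv": r.reference_effective_dose,
                "excl_arm": int(r.excluded_arm_position),
                "excl_metal": int(r.excluded_metal_implant),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of records removed by :func:`filter_cohort`, per reason.

    A record flagged for both arm position and metal counts in both flag
    tallies; ``n_nonpositive_dose`` counts otherwise-unflagged records
    removed by the positivity rule, so
    ``n_retained = n_input - n_flagged - n_nonpositive_dose``.
    """

    n_input: int
    n_retained: int
    n_arm: int
    n_metal: int
    n_flagged: int
    n_nonpositive_dose: int


def filter_cohort(cohort: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Drop flagged and non-positive-dose records; report counts per reason.

    Idempotent: filtering a filtered cohort removes nothing further.
    """
    kept, n_arm, n_metal, n_flagged, n_nonpos = [], 0, 0, 0, 0
    for r in cohort:
        flagged = r.excluded_arm_position or r.excluded_metal_implant
        n_arm += r.excluded_arm_position
        n_metal += r.excluded_metal_implant
        if flagged:
            n_flagged += 1
        elif r.reference_effective_dose <= 0:
            n_nonpos += 1
        else:
            kept.append(r)
    report = ExclusionReport(
        n_input=len(cohort),
        n_retained=len(kept),
        n_arm=n_arm,
        n_metal=n_metal,
        n_flagged=n_flagged,
        n_nonpositive_dose=n_nonpos,
    )
    return replace(cohort, records=tuple(kept)), report


def stratify(cohort: Cohort) -> dict[str, Cohort]:
    """Partition a cohort into male / female / both strata.

    ``both`` is the full cohort; the male and female strata are disjoint
    and their sizes sum to it.  Unknown sex labels are impossible for
    validated records, but the check is kept for frames built externally.
    """
    by_sex: dict[str, list[ExamRecord]] = {s: [] for s in SEXES}
    for r in cohort:
        if r.sex not in by_sex:
            raise ValueError(f"unknown sex label {r.sex!r}")
        by_sex[r.sex].append(r)
    out = {s: replace(cohort, records=tuple(by_sex[s])) for s in SEXES}
    out["both"] = cohort
    return out


def summarize(cohort: Cohort, sd_mode: str = "sample") -> pd.DataFrame:
    """Per-stratum sample counts and age mean +/- SD.

    ``sd_mode`` selects the sample (n-1 denominator, the cohort-description
    convention and the default) or population (n) standard deviation.
    Empty strata are omitted from the table; a ``note`` column records the
    omission on the remaining rows.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    ddof = 1 if sd_mode == "sample" else 0
    strata = stratify(cohort)
    rows, omitted = [], []
    for name in STRATA:
        sub = strata[name]
        if len(sub) == 0:
            omitted.append(name)
            continue
        ages = np.array([r.age for r in sub], dtype=float)
        sd = float(ages.std(ddof=ddof)) if len(ages) > ddof else 0.0
        rows.append(
            {"stratum": name, "n": len(sub), "age_mean": float(ages.mean()), "age_sd": sd}
        )
    df = pd.DataFrame(rows, columns=["stratum", "n", "age_mean", "age_sd"])
    df["note"] = f"omitted empty strata: {', '.join(omitted)}" if omitted else ""
    return df


# ---------------------------------------------------------------------------
# delimited-table I/O
# ---------------------------------------------------------------------------

def _record_from_row(row: pd.Series) -> ExamRecord:
    indices = ExamIndices(
        scan_length=float(row["scan_length_cm"]),
        dlp=float(row["dlp_mgycm"]),
        mean_ssde=float(row["mean_ssde_mgy"]),
        ssde_lp=float(row["ssde_lp_mgycm"]),
        n_slices=None,
    )
    return ExamRecord(
        exam_id=str(row["exam_id"]),
        sex=str(row["sex"]),
        age=float(row["age"]),
        indices=indices,
        reference_effective_dose=float(row["effective_dose_msv"]),
        excluded_arm_position=bool(int(row["excl_arm"])),
        excluded_metal_implant=bool(int(row["excl_metal"])),
    )


def read_cohort(path: str | Path, role: str, label: str = "") -> Cohort:
    """Read a cohort table; the role tag is supplied by the caller."""
    df = pd.read_csv(path, dtype={"exam_id": str, "sex": str})
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table {path} missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"cohort table {path}, row {i + 2}: {exc}") from exc
    return Cohort(records=tuple(records), role=role, label=label)


def _fmt(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return "%.10g" % float(value)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort table (UTF-8, LF, %.10g floats — round-trip stable)."""
    df = cohort.to_frame()
    lines = [",".join(COHORT_COLUMNS)]
    for _, row in df.iterrows():
        cells = [str(row["exam_id"]), str(row["sex"])] + [
            _fmt(row[c]) for c in COHORT_COLUMNS[2:]
        ]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
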