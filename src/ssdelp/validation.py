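"""Held-out verification of conversion coefficients.

Each conversion factor (the fixed conventional DLP factor, the fitted DLP
factor and the fitted SSDE-LP factor) is applied to a held-out validation
cohort and the signed discrepancy

    predicted effective dose  -  reference effective dose   (mSv)

is summarized per stratum as mean +/- SD.  The sign convention makes
underestimation negative.  Within a stratum the "applicable" factor is the
one fitted on that stratum (the both-sexes column applies the pooled factor
to every record), mirroring how a sex-specific coefficient would be used in
practice.

Factors are then ranked per stratum by absolute mean discrepancy, with SD
as the tie-breaking second key — the mean measures central accuracy, the
SD the stability of the estimate across body sizes.  Exact ties are
surfaced as ties, never broken silently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ConversionFactorSet, predict_effective_dose
from .cohort import Cohort, STRATA, stratify

__all__ = [
    "FACTOR_LABELS",
    "DiscrepancySummary",
    "compute_discrepancies",
    "summarize_discrepancies",
    "rank_factors",
    "format_discrepancy_table",
    "write_discrepancy_table",
]

#: Factor labels in display order, with the index each one multiplies.
FACTOR_LABELS = ("conventional", "k_dlp", "k_ssde_lp")
_FACTOR_INDEX = {"conventional": "dlp", "k_dlp": "dlp", "k_ssde_lp": "ssde_lp"}
_INDEX_COLUMN = {"dlp": "dlp_mgycm", "ssde_lp": "ssde_lp_mgycm"}


@dataclass(frozen=True)
class DiscrepancySummary:
    """Mean and SD of signed discrepancies for one (factor, stratum) cell."""

    factor_label: str
    stratum: str
    mean_discrepancy: float
    sd_discrepancy: float
    n: int

    def __post_init__(self) -> None:
        if self.sd_discrepancy < 0:
            raise ValueError("sd_discrepancy must be >= 0")


def compute_discrepancies(
    cohort: Cohort, factors: ConversionFactorSet
) -> pd.DataFrame:
    """Per-record signed differences (predicted - reference) for every factor.

    Returns a long-format frame with columns ``exam_id``, ``stratum``,
    ``factor_label``, ``predicted_msv``, ``reference_msv``,
    ``discrepancy_msv``.  Raises ``KeyError`` naming the gap if a needed
    fitted factor is missing.
    """
    strata = stratify(cohort)
    frames = []
    for stratum in STRATA:
        df = strata[stratum].to_frame()
        if df.empty:
            continue
        for label in FACTOR_LABELS:
            index_type = _FACTOR_INDEX[label]
            x = df[_INDEX_COLUMN[index_type]].to_numpy(dtype=float)
            if label == "conventional":
                pred = predict_effective_dose(factors.k_conventional, x)
            else:
                pred = predict_effective_dose(factors[(index_type, stratum)], x)
            frames.append(
                pd.DataFrame(
                    {
                        "exam_id": df["exam_id"].to_numpy(),
                        "stratum": stratum,
                        "factor_label": label,
                        "predicted_msv": pred,
                        "reference_msv": df["effective_dose_msv"].to_numpy(dtype=float),
                        "discrepancy_msv": pred
                        - df["effective_dose_msv"].to_numpy(dtype=float),
                    }
                )
            )
    if not frames:
        raise ValueError("validation cohort is empty")
    return pd.concat(frames, ignore_index=True)


def summarize_discrepancies(
    differences: pd.DataFrame, sd_mode: str = "sample"
) -> list[DiscrepancySummary]:
    """Collapse per-record differences into the factor x stratum grid.

    ``sd_mode`` follows the project-wide convention switch (sample SD,
    n-1 denominator, by default).  An empty (factor, stratum) cell raises
    ``ValueError`` naming the cell.
    """
    if sd_mode not in ("sample", "population"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    ddof = 1 if sd_mode == "sample" else 0
    present_strata = [s for s in STRATA if (differences["stratum"] == s).any()]
    out = []
    for label in FACTOR_LABELS:
        for stratum in present_strata:
            cell = differences.loc[
                (differences["factor_label"] == label)
                & (differences["stratum"] == stratum),
                "discrepancy_msv",
            ].to_numpy(dtype=float)
            if cell.size == 0:
                raise ValueError(f"no discrepancies for ({label}, {stratum})")
            sd = float(cell.std(ddof=ddof)) if cell.size > ddof else 0.0
            out.append(
                DiscrepancySummary(
                    factor_label=label,
                    stratum=stratum,
                    mean_discrepancy=float(cell.mean()),
                    sd_discrepancy=sd,
                    n=int(cell.size),
                )
            )
    return out


def rank_factors(
    summaries: list[DiscrepancySummary],
) -> dict[str, list[list[str]]]:
    """Order factors per stratum by |mean discrepancy|, then SD.

    Returns, per stratum, a list of rank groups: each group is a list of
    factor labels sharing identical (|mean|, SD) keys, so ties appear as
    multi-member groups rather than an arbitrary order.
    """
    by_stratum: dict[str, list[DiscrepancySummary]] = {}
    for s in summaries:
        by_stratum.setdefault(s.stratum, []).append(s)
    ranking: dict[str, list[list[str]]] = {}
    for stratum, cells in by_stratum.items():
        cells = sorted(
            cells, key=lambda c: (abs(c.mean_discrepancy), c.sd_discrepancy)
        )
        groups: list[list[str]] = []
        last_key = None
        for c in cells:
            key = (abs(c.mean_discrepancy), c.sd_discrepancy)
            if key == last_key:
                groups[-1].append(c.factor_label)
            else:
                groups.append([c.factor_label])
                last_key = key
        ranking[stratum] = groups
    return ranking


def format_discrepancy_table(summaries: list[DiscrepancySummary]) -> str:
    """Human-readable grid: rows are factors, columns strata, cells
    "mean +/- SD mSv"."""
    strata = [s for s in STRATA if any(c.stratum == s for c in summaries)]
    cells = {(c.factor_label, c.stratum): c for c in summaries}
    buf = io.StringIO()
    buf.write(f"{'factor':<16}" + "".join(f"{s + ' (mSv)':>22}" for s in strata) + "\n")
    for label in FACTOR_LABELS:
        row = []
        for stratum in strata:
            c = cells.get((label, stratum))
            row.append(
                f"{c.mean_discrepancy:+.1f} ± {c.sd_discrepancy:.1f}" if c else "—"
            )
        buf.write(f"{label:<16}" + "".join(f"{r:>22}" for r in row) + "\n")
    return buf.getvalue()


def write_discrepancy_table(
    summaries: list[DiscrepancySummary], path: str | Path
) -> None:
    """Write the summary grid as a TSV (full precision, %.10g)."""
    lines = ["factor_label\tstratum\tmean_discrepancy_msv\tsd_discrepancy_msv\tn"]
    for c in summaries:
        lines.append(
            f"{c.factor_label}\t{c.stratum}\t"
            f"{c.mean_discrepancy:.10g}\t{c.sd_discrepancy:.10g}\t{c.n}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
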