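"""Effective-dose conversion-coefficient calibration.

The conversion coefficient ``k`` for a dose index (DLP or SSDE-LP) is the
slope of a simple linear regression of the reference effective dose
(vertical axis, mSv) on the index (horizontal axis, mGy*cm), fitted per
stratum (male, female, both sexes).  Two model modes are provided:

``intercept``
    Ordinary least squares with a free intercept — the spreadsheet
    "simple regression" slope.  This is the default.
``origin``
    Least squares through the origin; the reported R^2 is then the
    uncentered coefficient of determination and is not comparable with
    intercept-mode R^2.

Prediction applies the slope only (``E = k * index``), never the fitted
intercept: a conversion coefficient is a multiplier by definition, and the
held-out verification arithmetic multiplies the index by ``k`` alone.  The
fixed conventional abdominopelvic factor ``k = 0.015 mSv/(mGy*cm)`` applied
to DLP is carried alongside the fitted factors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import statsmodels.api as sm
import yaml

from .cohort import Cohort, STRATA, stratify

__all__ = [
    "K_CONVENTIONAL",
    "INDEX_TYPES",
    "INDEX_COLUMNS",
    "MODEL_MODES",
    "ConversionFactor",
    "ConversionFactorSet",
    "fit_conversion_factor",
    "fit_all",
    "predict_effective_dose",
    "write_factor_set",
    "read_factor_set",
    "format_factor_table",
]

#: Conventional abdominopelvic DLP-to-effective-dose factor, mSv/(mGy*cm).
K_CONVENTIONAL: float = 0.015

INDEX_TYPES = ("dlp", "ssde_lp")
MODEL_MODES = ("intercept", "origin")

#: Cohort-table column holding each index.
INDEX_COLUMNS = {"dlp": "dlp_mgycm", "ssde_lp": "ssde_lp_mgycm"}


@dataclass(frozen=True)
class ConversionFactor:
    """A fitted conversion coefficient with its diagnostics.

    ``slope`` is in mSv per mGy*cm; ``intercept`` is 0 in origin mode.
    ``r_squared`` is the centred R^2 in intercept mode and the uncentered
    coefficient of determination in origin mode.
    """

    index_type: str
    stratum: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    model_mode: str

    def __post_init__(self) -> None:
        if self.index_type not in INDEX_TYPES:
            raise ValueError(f"unknown index_type {self.index_type!r}")
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.model_mode not in MODEL_MODES:
            raise ValueError(f"unknown model_mode {self.model_mode!r}")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")
        if self.n < 2:
            raise ValueError("a fit needs n >= 2")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


@dataclass(frozen=True)
class ConversionFactorSet:
    """Fitted factors keyed by (index_type, stratum) plus the fixed
    conventional constant; strata that could not be fitted are listed in
    ``gaps`` rather than silently skipped."""

    factors: dict[tuple[str, str], ConversionFactor]
    k_conventional: float = K_CONVENTIONAL
    gaps: tuple[str, ...] = ()

    def __getitem__(self, key: tuple[str, str]) -> ConversionFactor:
        try:
            return self.factors[key]
        except KeyError:
            raise KeyError(
                f"no fitted factor for index={key[0]!r}, stratum={key[1]!r}"
                + (f" (reported gaps: {list(self.gaps)})" if self.gaps else "")
            ) from None


def fit_conversion_factor(
    cohort: Cohort, index_type: str, stratum: str, model_mode: str = "intercept"
) -> ConversionFactor:
    """Fit one conversion coefficient for one stratum of a cohort.

    Raises ``ValueError`` for fewer than two usable records or a degenerate
    (constant) index column.
    """
    if index_type not in INDEX_TYPES:
        raise ValueError(f"unknown index_type {index_type!r}")
    if model_mode not in MODEL_MODES:
        raise ValueError(f"unknown model_mode {model_mode!r}")
    sub = stratify(cohort)[stratum]
    df = sub.to_frame()
    x = df[INDEX_COLUMNS[index_type]].to_numpy(dtype=float)
    y = df["effective_dose_msv"].to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError(
            f"stratum {stratum!r} has {len(x)} usable records; need >= 2"
        )
    if np.ptp(x) == 0:
        raise ValueError(
            f"degenerate fit for stratum {stratum!r}: all {index_type} values equal"
        )
    if model_mode == "intercept":
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = float(res.params[0]), float(res.params[1])
    else:
        res = sm.OLS(y, x[:, None]).fit()  # rsquared is uncentered here
        intercept, slope = 0.0, float(res.params[0])
    return ConversionFactor(
        index_type=index_type,
        stratum=stratum,
        slope=slope,
        intercept=intercept,
        r_squared=float(res.rsquared),
        n=len(x),
        model_mode=model_mode,
    )


def fit_all(cohort: Cohort, model_mode: str = "intercept") -> ConversionFactorSet:
    """Fit all six factors (2 indices x 3 strata) plus the conventional one.

    A stratum with fewer than two usable records becomes a reported gap;
    fitting continues for the others.
    """
    factors: dict[tuple[str, str], ConversionFactor] = {}
    gaps: list[str] = []
    for index_type in INDEX_TYPES:
        for stratum in STRATA:
            try:
                factors[(index_type, stratum)] = fit_conversion_factor(
                    cohort, index_type, stratum, model_mode
                )
            except ValueError as exc:
                gaps.append(f"{index_type}/{stratum}: {exc}")
    return ConversionFactorSet(factors=factors, gaps=tuple(gaps))


def predict_effective_dose(
    factor: ConversionFactor | float, index_value
) -> float | np.ndarray:
    """Predicted effective dose ``k * index`` in mSv.

    ``factor`` is a fitted :class:`ConversionFactor` (its slope is used —
    the intercept is deliberately not applied) or a bare coefficient such
    as :data:`K_CONVENTIONAL`.  ``index_value`` may be a scalar or array
    of non-negative mGy*cm values.
    """
    k = factor.slope if isinstance(factor, ConversionFactor) else float(factor)
    x = np.asarray(index_value, dtype=float)
    if np.any(x < 0):
        raise ValueError("index values must be >= 0")
    out = k * x
    return float(out) if np.isscalar(index_value) else out


# ---------------------------------------------------------------------------
# serialization and display
# ---------------------------------------------------------------------------

def _factor_dict(f: ConversionFactor) -> dict:
    return {
        "slope": float(f.slope),
        "intercept": float(f.intercept),
        "r_squared": float(f.r_squared),
        "n": int(f.n),
        "model_mode": f.model_mode,
    }


def write_factor_set(fs: ConversionFactorSet, path: str | Path) -> None:
    """Serialize a factor set as a YAML document with stable key order."""
    doc = {
        "k_conventional": float(fs.k_conventional),
        "factors": {
            index_type: {
                stratum: _factor_dict(fs.factors[(index_type, stratum)])
                for stratum in STRATA
                if (index_type, stratum) in fs.factors
            }
            for index_type in INDEX_TYPES
        },
        "gaps": list(fs.gaps),
    }
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def read_factor_set(path: str | Path) -> ConversionFactorSet:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    factors = {}
    for index_type, strata in (doc.get("factors") or {}).items():
        for stratum, d in (strata or {}).items():
            factors[(index_type, stratum)] = ConversionFactor(
                index_type=index_type, stratum=stratum, **d
            )
    return ConversionFactorSet(
        factors=factors,
        k_conventional=float(doc.get("k_conventional", K_CONVENTIONAL)),
        gaps=tuple(doc.get("gaps", ())),
    )


def format_factor_table(fs: ConversionFactorSet, decimals: int = 3) -> str:
    """Human-readable factor grid (rows: factors; columns: strata).

    Slopes are rounded for display only; serialized and in-memory values
    keep full precision.
    """
    buf = io.StringIO()
    head = f"{'factor':<16}" + "".join(f"{s:>22}" for s in STRATA) + f"{'target':>10}"
    buf.write(head + "\n")
    buf.write(
        f"{'k_conventional':<16}"
        + "".join(f"{fs.k_conventional:>22.{decimals}f}" for _ in STRATA)
        + f"{'DLP':>10}\n"
    )
    for index_type, label, target in (
        ("dlp", "k_dlp", "DLP"),
        ("ssde_lp", "k_ssde_lp", "SSDE-LP"),
    ):
        cells = []
        for stratum in STRATA:
            f = fs.factors.get((index_type, stratum))
            cells.append(
                f"{f.slope:.{decimals}f} (R2={f.r_squared:.3f})" if f else "—"
            )
        buf.write(f"{label:<16}" + "".join(f"{c:>22}" for c in cells) + f"{target:>10}\n")
    if fs.gaps:
        buf.write("gaps:\n")
        for g in fs.gaps:
            buf.write(f"  - {g}\n")
    return buf.getvalue()
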