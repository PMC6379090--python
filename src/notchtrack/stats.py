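"""Count-level statistics for fixed-brain quantifications.

Summaries follow box-plot conventions (median, quartiles by linear
interpolation, whiskers at +/-1.5 x IQR clipped to the data range), group
comparisons use the unequal-variance (Welch) two-sided t-test with the
conventional star bands, and fold changes are ratios of condition means
presented at one decimal.  Experimental counts (cells per nerve cord, cells
per lineage) are inputs to this module, never outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InputError


@dataclass(frozen=True)
class CountSample:
    """Replicate counts for one condition."""

    condition: str
    values: tuple
    batch: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 1:
            raise InputError("a CountSample needs at least one replicate")
        if np.any(v < 0):
            raise InputError("counts must be non-negative")
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class CountSummary:
    n: int
    mean: float
    sem: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float


def summarize_counts(sample: CountSample) -> CountSummary:
    """Mean +/- SEM (sample SD, n-1) and the box-plot five-number summary;
    whiskers are q1 - 1.5 IQR and q3 + 1.5 IQR clipped to the data range."""
    v = sample.array
    n = v.size
    q1, med, q3 = (float(np.percentile(v, q)) for q in (25, 50, 75))
    iqr = q3 - q1
    sem = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return CountSummary(
        n=int(n), mean=float(v.mean()), sem=sem, median=med, q1=q1, q3=q3, iqr=iqr,
        whisker_low=float(max(v.min(), q1 - 1.5 * iqr)),
        whisker_high=float(min(v.max(), q3 + 1.5 * iqr)),
    )


@dataclass(frozen=True)
class FoldChange:
    value: float

    @property
    def presentation(self) -> float:
        return round(self.value, 1)

    def __str__(self) -> str:
        return f"{self.presentation:.1f}-fold"


def fold_change(mean_numerator: float, mean_denominator: float) -> FoldChange:
    """Ratio of two condition means, e.g. total marker-positive cells per
    nerve cord between genotypes."""
    if not mean_denominator > 0:
        raise InputError(f"denominator must be > 0, got {mean_denominator}")
    return FoldChange(value=float(mean_numerator) / float(mean_denominator))


def star_band(p_value: float) -> str:
    """Conventional nested significance stars (two-sided)."""
    if p_value < 1e-4:
        return "****"
    if p_value < 1e-3:
        return "***"
    if p_value < 1e-2:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def compare_groups(a: CountSample, b: CountSample) -> tuple[float, float, str]:
    """Welch's unequal-variance two-sample t-test (two-sided) with star band."""
    if len(a.values) < 2 or len(b.values) < 2:
        raise InputError("each group needs n >= 2")
    t, p = sps.ttest_ind(a.array, b.array, equal_var=False)
    if np.isnan(t):  # zero variance in both groups with equal means
        t, p = 0.0, 1.0
    return float(t), float(p), star_band(float(p))


def read_counts_csv(path) -> dict[str, CountSample]:
    """Read replicate counts from a long-format CSV with columns
    (condition, specimen, value, batch); one CountSample per condition."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"condition", "value"} - set(df.columns)
    if missing:
        raise InputError(f"counts CSV lacks column(s) {sorted(missing)}")
    out = {}
    for cond, grp in df.groupby("condition", sort=True):
        batches = grp["batch"].unique() if "batch" in grp else []
        out[str(cond)] = CountSample(
            condition=str(cond), values=tuple(grp["value"].astype(float)),
            batch=str(batches[0]) if len(batches) == 1 else None)
    return out


def hyperplasia_fraction(flags_by_specimen: dict[str, list[bool]]
                         ) -> tuple[dict[str, float], CountSummary]:
    """Percent of flagged lineages per specimen, plus a summary over
    specimens (for 'percent hyperplastic lineages per nerve cord' plots)."""
    if not flags_by_specimen:
        raise DegenerateInputError("no specimens")
    percents: dict[str, float] = {}
    for spec, flags in flags_by_specimen.items():
        if len(flags) == 0:
            raise DegenerateInputError(f"specimen {spec!r} has zero lineages")
        percents[spec] = 100.0 * sum(bool(f) for f in flags) / len(flags)
    pooled = summarize_counts(CountSample("pooled", tuple(percents.values())))
    return percents, pooled
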