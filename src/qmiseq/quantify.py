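"""Spike-in internal-standard calibration and read-to-copy conversion.

The quantitative metabarcoding workflow adds a ladder of synthetic internal
standard DNAs at known copies/µl to every library.  Because the standards
pass through the same PCR and sequencing as the real templates, the number
of reads each standard receives is (to first order) proportional to its
input copy number, with a *sample-specific* proportionality constant (the
amplification slope).  Regressing standard reads on standard copies with the
intercept fixed at zero yields that slope; dividing a fish OTU's reads by it
converts reads to copies/µl of DNA extract, and the filtration/elution
volumes convert extract concentration to copies/ml of sampled water.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default spike-in ladder: five standards at two-fold-ish dilutions (copies/µl).
DEFAULT_STANDARD_LADDER = (
    ("Std_A", 100.0),
    ("Std_B", 50.0),
    ("Std_C", 25.0),
    ("Std_D", 12.5),
    ("Std_E", 2.5),
)


@dataclass(frozen=True)
class StandardSpec:
    """The spike-in ladder: standard id -> input concentration (copies/µl)."""

    entries: tuple[tuple[str, float], ...] = DEFAULT_STANDARD_LADDER

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValueError("need at least two internal standards")
        ids = [sid for sid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("standard ids must be unique")
        copies = [c for _, c in self.entries]
        if any(c <= 0 for c in copies):
            raise ValueError("standard copies must be strictly positive")
        if len(set(copies)) != len(copies):
            raise ValueError("standard concentrations must be distinct")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.entries)

    @property
    def copies(self) -> np.ndarray:
        return np.array([c for _, c in self.entries], dtype=float)

    def as_mapping(self) -> dict[str, float]:
        return dict(self.entries)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample field metadata needed for volume conversion and modelling."""

    sample_id: str
    station_id: str
    distance_m: float  # absolute distance from the focal reef, metres
    depth_layer: str  # "middle" or "bottom"
    replicate: int
    filtered_volume_ml: float = 2000.0
    elution_volume_ul: float = 100.0
    sampling_time: str = ""
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.filtered_volume_ml <= 0:
            raise ValueError("filtered_volume_ml must be positive")
        if self.elution_volume_ul <= 0:
            raise ValueError("elution_volume_ul must be positive")
        if self.depth_layer not in ("middle", "bottom"):
            raise ValueError(f"unknown depth layer {self.depth_layer!r}")


@dataclass
class ReadTable:
    """Samples × OTUs integer read counts, with standard OTUs flagged.

    ``counts`` is a DataFrame indexed by sample id with one column per OTU;
    ``standard_ids`` names the columns that hold internal-standard reads.
    """

    counts: pd.DataFrame
    standard_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("read counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("read counts must be integers")
        missing = set(self.standard_ids) - set(self.counts.columns)
        if missing:
            raise ValueError(f"standard columns missing from table: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def fish_ids(self) -> list[str]:
        std = set(self.standard_ids)
        return [c for c in self.counts.columns if c not in std]

    def standard_reads(self, sample_id: str) -> dict[str, int]:
        row = self.counts.loc[sample_id, list(self.standard_ids)]
        return {k: int(v) for k, v in row.items()}

    def fish_counts(self) -> pd.DataFrame:
        return self.counts[self.fish_ids]

    def copy(self) -> "ReadTable":
        return ReadTable(self.counts.copy(), tuple(self.standard_ids))


@dataclass(frozen=True)
class CalibrationResult:
    """Zero-intercept regression of standard reads on standard copies."""

    sample_id: str
    slope: float  # reads per (copy/µl)
    r_squared: float  # uncentered R², in [0, 1]
    n_standards: int
    flagged: bool = False
    flag_reason: str | None = None


@dataclass
class QuantTable:
    """Quantified fish OTU table in copies/µl extract and copies/ml water."""

    copies_per_ul_extract: pd.DataFrame
    copies_per_ml_water: pd.DataFrame
    provenance: pd.DataFrame  # per sample: slope, r_squared, volumes


def fit_standard_curve(
    standard_reads: Mapping[str, float],
    spec: StandardSpec,
    sample_id: str = "",
) -> CalibrationResult:
    """Fit reads = slope × copies with the intercept fixed at zero.

    The least-squares zero-intercept estimator is slope = Σxy / Σx² and the
    goodness of fit is the uncentered R² = 1 − RSS/Σy² (the centred version
    is not meaningful when the regression is forced through the origin).
    All-zero standard reads yield a flagged result with slope 0 rather than
    an exception, so a whole run is never brought down by one failed library.
    """
    missing = [sid for sid in spec.ids if sid not in standard_reads]
    if missing:
        raise KeyError(f"standard reads missing for {missing} (sample {sample_id!r})")
    x = spec.copies
    y = np.array([float(standard_reads[sid]) for sid in spec.ids])
    if (y < 0).any():
        raise ValueError("standard reads must be non-negative")
    if not y.any():
        return CalibrationResult(
            sample_id, 0.0, 0.0, len(x), flagged=True, flag_reason="all_zero_standards"
        )
    slope = float(np.sum(x * y) / np.sum(x * x))
    rss = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - rss / float(np.sum(y * y))
    return CalibrationResult(sample_id, slope, float(np.clip(r2, 0.0, 1.0)), len(x))


def convert_reads_to_copies(reads: float, cal: CalibrationResult) -> float:
    """Reads → copies/µl via the sample-specific slope (reads / slope)."""
    if cal.flagged or cal.slope <= 0:
        raise ValueError(
            f"cannot quantify sample {cal.sample_id!r}: "
            f"calibration flagged ({cal.flag_reason or 'non-positive slope'})"
        )
    if reads < 0:
        raise ValueError("reads must be non-negative")
    return reads / cal.slope


def copies_per_ml_water(copies_per_ul: float, meta: SampleMeta) -> float:
    """Extract concentration → water concentration.

    The whole filter is eluted into ``elution_volume_ul`` of buffer, so the
    total copy yield is copies/µl × elution volume; dividing by the filtered
    water volume gives copies per ml of seawater.
    """
    if copies_per_ul < 0:
        raise ValueError("copies_per_ul must be non-negative")
    return copies_per_ul * meta.elution_volume_ul / meta.filtered_volume_ml


def quantify_table(
    read_table: ReadTable,
    spec: StandardSpec,
    metas: Sequence[SampleMeta],
    r2_qc_floor: float = 0.7,
) -> tuple[QuantTable, list[CalibrationResult]]:
    """Calibrate every sample and convert all fish OTU reads to copies.

    Every sample — including negative controls, which carry standards but
    should carry no fish DNA — gets a calibration.  Controls are *not*
    converted into the quantified table; their contamination level is
    reported separately (see :func:`negative_control_contamination`).
    Samples whose calibration is flagged (all-zero standards) are excluded
    from the quantified table with a logged warning.  Samples whose R² falls
    below ``r2_qc_floor`` are flagged in the provenance table but kept.
    """
    meta_by_id = {m.sample_id: m for m in metas}
    missing = set(read_table.sample_ids) - set(meta_by_id)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    if set(spec.ids) != set(read_table.standard_ids):
        raise ValueError("standard ids in table do not match the standard spec")

    cals: list[CalibrationResult] = []
    rows_ul: dict[str, pd.Series] = {}
    prov_rows: list[dict] = []
    fish = read_table.fish_counts()
    for sid in read_table.sample_ids:
        cal = fit_standard_curve(read_table.standard_reads(sid), spec, sample_id=sid)
        cals.append(cal)
        meta = meta_by_id[sid]
        qc_flag = (not cal.flagged) and cal.r_squared < r2_qc_floor
        prov_rows.append(
            {
                "sample_id": sid,
                "slope": cal.slope,
                "r_squared": cal.r_squared,
                "n_standards": cal.n_standards,
                "calibration_flagged": cal.flagged,
                "below_r2_floor": qc_flag,
                "is_control": meta.is_control,
                "filtered_volume_ml": meta.filtered_volume_ml,
                "elution_volume_ul": meta.elution_volume_ul,
            }
        )
        if cal.flagged:
            logger.warning(
                "sample %s excluded from quantification: %s", sid, cal.flag_reason
            )
            continue
        if qc_flag:
            logger.warning(
                "sample %s calibration R²=%.3f below QC floor %.2f (kept, flagged)",
                sid, cal.r_squared, r2_qc_floor,
            )
        if meta.is_control:
            continue
        rows_ul[sid] = fish.loc[sid].astype(float) / cal.slope

    ul = pd.DataFrame(rows_ul).T
    ul.index.name = "sample_id"
    if ul.empty:
        ul = pd.DataFrame(columns=fish.columns, dtype=float)
    ml = ul.copy()
    for sid in ml.index:
        m = meta_by_id[sid]
        ml.loc[sid] = ul.loc[sid] * m.elution_volume_ul / m.filtered_volume_ml
    prov = pd.DataFrame(prov_rows).set_index("sample_id")
    return QuantTable(ul, ml, prov), cals


def negative_control_contamination(
    read_table: ReadTable,
    cals: Iterable[CalibrationResult],
    metas: Sequence[SampleMeta],
) -> float:
    """Field-blank contamination as % of the mean positive-sample copy yield.

    Converts the control's fish reads with its own slope, sums copies, and
    expresses the sum as a percentage of the mean total copies across
    positive (non-control) samples.  A clean run reports 0.0.
    """
    meta_by_id = {m.sample_id: m for m in metas}
    cal_by_id = {c.sample_id: c for c in cals}
    fish = read_table.fish_counts()

    control_total = 0.0
    positive_totals = []
    for sid in read_table.sample_ids:
        cal = cal_by_id.get(sid)
        if cal is None or cal.flagged:
            continue
        total = float(fish.loc[sid].sum()) / cal.slope
        if meta_by_id[sid].is_control:
            control_total += total
        else:
            positive_totals.append(total)
    if not positive_totals:
        raise ValueError("no positive samples to normalise against")
    mean_positive = float(np.mean(positive_totals))
    if mean_positive == 0:
        return 0.0 if control_total == 0 else math.inf
    return 100.0 * control_total / mean_positive


def nonstandard_read_fraction(fish_reads: float, total_reads: float) -> float:
    """Fraction (%) of reads assigned to real (non-standard) fish templates."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if fish_reads < 0 or fish_reads > total_reads:
        raise ValueError("fish_reads must lie in [0, total_reads]")
    return 100.0 * fish_reads / total_reads


def read_accounting(read_table: ReadTable) -> pd.DataFrame:
    """Per-sample totals of fish vs standard reads and the fish percentage."""
    fish = read_table.fish_counts().sum(axis=1)
    std = read_table.counts[list(read_table.standard_ids)].sum(axis=1)
    total = fish + std
    pct = np.where(total > 0, 100.0 * fish / total.replace(0, np.nan), np.nan)
    return pd.DataFrame(
        {
            "fish_reads": fish.astype(int),
            "standard_reads": std.astype(int),
            "total_reads": total.astype(int),
            "fish_pct": pct,
        }
    )
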