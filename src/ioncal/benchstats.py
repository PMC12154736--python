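"""Acquisition-timing and quantitative-precision benchmark statistics.

Timing metrics (acquisition rate, per-scan overhead, DIA cycle time)
operate on spectrum lists from :mod:`ioncal.msio`; precision metrics
(replicate CVs, log-abundance distribution modes, pairwise log2 ratios)
operate on analyte x replicate abundance tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msio import SpectrumRecord

__all__ = [
    "TimingSummary",
    "ReplicateQuantTable",
    "acquisition_rate",
    "acquisition_overhead",
    "cycle_time",
    "timing_summary",
    "cv_table",
    "CvResult",
    "distribution_mode",
    "pairwise_log2_ratio",
]


@dataclass
class TimingSummary:
    n_spectra: int
    total_time: float  # seconds, first to last scan start
    acquisition_rate: float  # Hz
    mean_scan_period: float  # milliseconds
    set_injection_time: float  # milliseconds
    overhead: float  # milliseconds
    cycle_time: float | None  # seconds; None when no DIA cycle detected


@dataclass
class ReplicateQuantTable:
    """Non-negative analyte x replicate abundances; NaN marks missing."""

    abundances: pd.DataFrame  # index: analyte_id, columns: replicate_id

    def __post_init__(self) -> None:
        if (self.abundances < 0).any().any():
            raise ValueError("abundances must be non-negative")

    @classmethod
    def from_tsv(cls, path) -> "ReplicateQuantTable":
        df = pd.read_csv(path, sep="\t")
        if "analyte_id" not in df.columns:
            raise ValueError("quant table missing column: analyte_id")
        if df.shape[1] < 3:
            raise ValueError("quant table needs at least 2 replicate columns")
        return cls(df.set_index("analyte_id").astype(float))

    @property
    def analyte_ids(self):
        return list(self.abundances.index)

    @property
    def replicate_ids(self):
        return list(self.abundances.columns)


def _rt_seconds(spectra) -> np.ndarray:
    return np.asarray([s.retention_time for s in spectra]) * 60.0


def acquisition_rate(spectra: list[SpectrumRecord]) -> float:
    """Spectra per second: count divided by the retention-time span."""
    if len(spectra) < 2:
        raise ValueError("acquisition rate needs at least 2 spectra")
    rt = _rt_seconds(spectra)
    span = rt[-1] - rt[0]
    if span <= 0:
        raise ValueError("retention times do not span a positive interval")
    return len(spectra) / span


def acquisition_overhead(
    spectra: list[SpectrumRecord], set_injection_time: float
) -> float:
    """Mean scan-to-scan period minus the method's set injection time, ms.

    The scan-to-scan period is used because per-scan duration metadata
    is not reliably present in mzML.
    """
    if len(spectra) < 2:
        raise ValueError("overhead needs at least 2 spectra")
    rt = _rt_seconds(spectra)
    mean_period_ms = float(np.diff(rt).mean()) * 1e3
    return mean_period_ms - set_injection_time


def cycle_time(
    spectra: list[SpectrumRecord], precursor_range: tuple[float, float]
) -> float:
    """Median time (s) between revisits of the lowest isolation window.

    The cycle is anchored at the lowest-m/z isolation window inside
    ``precursor_range``; the median of the gaps between its successive
    occurrences resists occasional dropped scans.
    """
    lo, hi = precursor_range
    centers = np.asarray([s.isolation_center for s in spectra])
    in_range = np.isfinite(centers) & (centers >= lo) & (centers <= hi)
    if not in_range.any():
        raise ValueError(f"no isolation windows inside {precursor_range}")
    anchor = centers[in_range].min()
    times = _rt_seconds(spectra)[np.isclose(centers, anchor)]
    if times.size < 2:
        raise ValueError("precursor range never revisited; cannot measure a cycle")
    return float(np.median(np.diff(np.sort(times))))


def timing_summary(
    spectra: list[SpectrumRecord],
    set_injection_time: float,
    precursor_range: tuple[float, float] | None = None,
) -> TimingSummary:
    rate = acquisition_rate(spectra)
    rt = _rt_seconds(spectra)
    total = float(rt[-1] - rt[0])
    mean_period = float(np.diff(rt).mean()) * 1e3
    cyc = None
    if precursor_range is not None:
        cyc = cycle_time(spectra, precursor_range)
    return TimingSummary(
        n_spectra=len(spectra),
        total_time=total,
        acquisition_rate=rate,
        mean_scan_period=mean_period,
        set_injection_time=set_injection_time,
        overhead=mean_period - set_injection_time,
        cycle_time=cyc,
    )


@dataclass
class CvResult:
    per_analyte: pd.Series  # CV in percent, indexed by analyte_id
    median_cv: float
    n_skipped: int  # analytes with <2 replicates or zero mean


def cv_table(table: ReplicateQuantTable, normalize: bool = False) -> CvResult:
    """Per-analyte coefficient of variation across replicates, percent.

    With ``normalize``, each replicate column is divided by its median
    abundance and multiplied by the grand median (the median over all
    non-missing values), so normalized values stay on the original
    scale. CV = 100 * sd / mean on the linear scale, sd with the n-1
    denominator; analytes with fewer than 2 non-missing replicates or a
    zero mean are skipped and counted.
    """
    df = table.abundances.astype(float)
    if normalize:
        col_medians = df.median(axis=0, skipna=True)
        grand = float(np.nanmedian(df.to_numpy()))
        df = df.div(col_medians, axis=1) * grand
    n_obs = df.notna().sum(axis=1)
    mean = df.mean(axis=1, skipna=True)
    sd = df.std(axis=1, ddof=1, skipna=True)
    valid = (n_obs >= 2) & (mean > 0)
    cv = 100.0 * sd[valid] / mean[valid]
    return CvResult(
        per_analyte=cv,
        median_cv=float(cv.median()) if len(cv) else float("nan"),
        n_skipped=int((~valid).sum()),
    )


def distribution_mode(values, kde: bool = False) -> float:
    """Mode of a positive-valued distribution, estimated on log10 scale.

    Histogram of log10(values) with Freedman-Diaconis bin width; the
    mode is 10**(center of the highest-count bin), ties resolved to the
    lower bin. ``kde=True`` instead returns the peak of a Gaussian KDE
    on log10(values).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError("mode estimation needs at least 10 values")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("values must be positive and finite")
    logv = np.log10(v)
    if np.ptp(logv) == 0:
        return float(v[0])
    if kde:
        from scipy.stats import gaussian_kde

        kd = gaussian_kde(logv)
        grid = np.linspace(logv.min(), logv.max(), 512)
        return float(10 ** grid[np.argmax(kd(grid))])
    counts, edges = np.histogram(logv, bins="fd")
    i = int(np.argmax(counts))  # first maximum == lower bin on ties
    center = 0.5 * (edges[i] + edges[i + 1])
    return float(10**center)


def pairwise_log2_ratio(
    table_a: ReplicateQuantTable, table_b: ReplicateQuantTable
) -> pd.Series:
    """log2(B/A) of per-analyte mean abundances over shared analytes.

    Only analytes present in both tables with strictly positive mean
    abundance contribute; an empty intersection is an error.
    """
    mean_a = table_a.abundances.mean(axis=1, skipna=True)
    mean_b = table_b.abundances.mean(axis=1, skipna=True)
    shared = mean_a.index.intersection(mean_b.index)
    shared = [a for a in shared if mean_a[a] > 0 and mean_b[a] > 0]
    if not shared:
        raise ValueError("no shared analytes with positive abundance")
    return np.log2(mean_b[shared] / mean_a[shared])
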