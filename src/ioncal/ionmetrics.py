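"""Per-analyte ion-count metrics from DIA chromatograms.

Mirrors the document-grid ion-count report columns: apex and LC-peak
ion counts for the analyte's transitions and for the whole spectrum
(TIC), raw (alpha = 1) or calibrated by an instrument alpha factor.

The two quoted definitions are the apex total ion count (TIC x
injection time at the apex scan) and the LC peak analyte ion count
(sum of transition-intensity x injection-time products over in-boundary
scans). The companion metrics — apex analyte ion count, LC peak total
ion count, and the LC peak TIC area — are reconstructed by direct
analogy and flagged as such here: their exact report-column formulas
were not published in the main text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .msio import Chromatogram, TransitionTarget

__all__ = ["IonMetricsRecord", "find_apex", "compute_ion_metrics", "protein_rollup"]


@dataclass
class IonMetricsRecord:
    """Ion-count metrics for one analyte.

    All *_ion_count fields are in ions (intensity x seconds / alpha);
    lc_peak_tic_area is a raw area in intensity x minutes and is not
    alpha-corrected.
    """

    analyte_id: str
    apex_rt: float  # minutes
    apex_total_ion_count: float
    apex_analyte_ion_count: float
    lc_peak_analyte_ion_count: float
    lc_peak_total_ion_count: float
    lc_peak_tic_area: float
    n_scans_in_boundary: int
    alpha_applied: float


def _boundary_mask(chrom: Chromatogram, boundary: tuple[float, float]) -> np.ndarray:
    lo, hi = boundary
    if not lo < hi:
        raise ValueError(f"{chrom.analyte_id}: invalid boundary {boundary}")
    # closed interval, matching document-grid peak-boundary semantics
    return (chrom.retention_times >= lo) & (chrom.retention_times <= hi)


def find_apex(chrom: Chromatogram, boundary: tuple[float, float]) -> int:
    """Index of the in-boundary scan with maximal summed transition
    intensity; ties go to the earliest retention time.

    The apex is sought inside the boundary only, so a co-eluting
    interference outside the integration window cannot capture it.
    """
    mask = _boundary_mask(chrom, boundary)
    if not mask.any():
        raise ValueError(
            f"{chrom.analyte_id}: no scans inside boundary "
            f"[{boundary[0]:g}, {boundary[1]:g}] min"
        )
    idx = np.flatnonzero(mask)
    # argmax returns the first maximum; retention times are ascending
    return int(idx[np.argmax(chrom.intensities[mask])])


def compute_ion_metrics(
    chrom: Chromatogram, target: TransitionTarget, alpha: float = 1.0
) -> IonMetricsRecord:
    """Compute the five ion-count metrics for one analyte.

    With t the per-scan injection time in seconds and the boundary a
    closed retention-time interval:

    - apex_total_ion_count      = tic(apex) * t(apex) / alpha
    - apex_analyte_ion_count    = transition_sum(apex) * t(apex) / alpha
    - lc_peak_analyte_ion_count = sum_in-boundary transition_sum * t / alpha
    - lc_peak_total_ion_count   = sum_in-boundary tic * t / alpha
    - lc_peak_tic_area          = trapezoidal integral of tic over rt
                                  (minutes), no alpha, no t

    alpha = 1 gives the uncalibrated (raw report) values.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    boundary = (target.boundary_start, target.boundary_end)
    apex = find_apex(chrom, boundary)
    mask = _boundary_mask(chrom, boundary)
    t_sec = chrom.injection_times * 1e-3
    apex_t = t_sec[apex]
    tic_area = 0.0
    if mask.sum() >= 2:
        tic_area = float(
            np.trapezoid(chrom.tics[mask], chrom.retention_times[mask])
        )
    return IonMetricsRecord(
        analyte_id=chrom.analyte_id,
        apex_rt=float(chrom.retention_times[apex]),
        apex_total_ion_count=float(chrom.tics[apex] * apex_t / alpha),
        apex_analyte_ion_count=float(chrom.intensities[apex] * apex_t / alpha),
        lc_peak_analyte_ion_count=float(
            np.sum(chrom.intensities[mask] * t_sec[mask]) / alpha
        ),
        lc_peak_total_ion_count=float(np.sum(chrom.tics[mask] * t_sec[mask]) / alpha),
        lc_peak_tic_area=tic_area,
        n_scans_in_boundary=int(mask.sum()),
        alpha_applied=float(alpha),
    )


def protein_rollup(records: Sequence[IonMetricsRecord]) -> float:
    """Protein-level ion count: summed LC peak analyte ion counts of the
    protein's peptides."""
    return float(sum(r.lc_peak_analyte_ion_count for r in records))
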