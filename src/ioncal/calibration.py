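"""Instrument response calibration from fragment-ratio shot noise.

The measured intensity of a fragment is modeled as I = alpha * N / t,
where N is the number of detected ions, t the ion injection time in
seconds, and alpha an instrument-specific scale factor. For two
fragments a and b measured in the same spectrum, the intensity ratio
R = I_a / I_b is free of alpha and t, and ion counting being Poisson
gives its variance as

    sigma_T^2 = alpha * Rbar^2 * (1/(Ibar_a * tbar) + 1/(Ibar_b * tbar))
                + sigma_o^2

so regressing the observed ratio variance (y) on the predictor
x = Rbar^2 * (1/(Ibar_a tbar) + 1/(Ibar_b tbar)) across several
fragment pairs estimates alpha as the slope and the non-Poisson noise
floor sigma_o^2 as the intercept. An alpha of 1 means intensities are
already in ions per second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .msio import FragmentIntensityMatrix, FragmentPanel

__all__ = [
    "RatioPairStatistics",
    "CalibrationFit",
    "compute_ratio_statistics",
    "fit_calibration",
    "calibrate_ions",
]

#: below this many co-detected spectra the sample variance of the ratio is
#: itself too noisy to regress on
DEFAULT_MIN_SPECTRA = 100


@dataclass(frozen=True)
class RatioPairStatistics:
    """Summary of one target/reference fragment intensity-ratio series.

    ``predictor`` is ``mean_ratio**2 * (1/(Ia*t) + 1/(Ib*t))`` with the
    mean injection time ``t`` in seconds — the inverse of the summed
    uncalibrated mean ion counts of the pair, scaled by the squared mean
    ratio.
    """

    target_mz: float
    reference_mz: float
    n_used: int
    mean_ratio: float
    total_variance: float
    mean_intensity_a: float
    mean_intensity_b: float
    mean_injection_time: float  # seconds
    predictor: float

    def __post_init__(self) -> None:
        if self.n_used < 2:
            raise ValueError("ratio statistics need at least 2 spectra")
        if not (self.mean_ratio > 0 and self.predictor > 0):
            raise ValueError("mean ratio and predictor must be positive")
        if self.total_variance < 0:
            raise ValueError("variance cannot be negative")
        expected = self.mean_ratio**2 * (
            1.0 / (self.mean_intensity_a * self.mean_injection_time)
            + 1.0 / (self.mean_intensity_b * self.mean_injection_time)
        )
        if not np.isclose(self.predictor, expected, rtol=1e-12):
            raise ValueError("predictor inconsistent with its own fields")


@dataclass
class CalibrationFit:
    """OLS fit of ratio variance against the Poisson predictor.

    alpha : slope — multiply ions/sec by 1/alpha to calibrate.
    sigma0_sq : intercept — variance not explained by ion counting.
    alpha_se : OLS standard error of the slope (NaN with 2 points,
        where the residual degrees of freedom are zero).
    """

    alpha: float
    alpha_se: float
    sigma0_sq: float
    r_squared: float
    n_points: int
    sigma0_se: float = float("nan")
    points: list = field(default_factory=list)

    def refit(self) -> "CalibrationFit":
        """Refit from the stored points; reproduces alpha/sigma0_sq."""
        return fit_calibration(self.points)


def compute_ratio_statistics(
    matrix: FragmentIntensityMatrix,
    panel: FragmentPanel,
    min_spectra: int = DEFAULT_MIN_SPECTRA,
    mad_trim: float | None = None,
) -> list[RatioPairStatistics]:
    """Per-spectrum target/reference intensity ratios, summarized per pair.

    For each non-reference panel fragment, only spectra where both the
    target and the reference intensity are strictly positive are used.
    The per-spectrum ratio is I_target / I_reference; ``mean_ratio`` and
    ``total_variance`` are the sample mean and (n-1)-denominator sample
    variance of those ratios. The predictor uses the pair's mean
    intensities and the mean injection time over the retained spectra,
    converted to seconds.

    Parameters
    ----------
    min_spectra : int
        Pairs retained in fewer spectra are dropped with a warning.
    mad_trim : float, optional
        If set, discard per-spectrum ratios farther than this many
        median-absolute-deviations from the median ratio before
        summarizing (off by default; no trimming is the reference
        behavior).
    """
    ref_idx = int(np.argmin(np.abs(matrix.fragment_mzs - panel.reference_mz)))
    if not np.isclose(matrix.fragment_mzs[ref_idx], panel.reference_mz):
        raise ValueError("reference fragment not present in intensity matrix")
    ref = matrix.values[:, ref_idx]
    out: list[RatioPairStatistics] = []
    for j, mz in enumerate(matrix.fragment_mzs):
        if j == ref_idx:
            continue
        tgt = matrix.values[:, j]
        keep = (tgt > 0) & (ref > 0)
        n = int(keep.sum())
        if n < min_spectra:
            warnings.warn(
                f"fragment {mz:.4f}: only {n} spectra with both ions detected "
                f"(< {min_spectra}); pair dropped",
                stacklevel=2,
            )
            continue
        ratios = tgt[keep] / ref[keep]
        t_sec = matrix.injection_times[keep] * 1e-3
        ia = tgt[keep]
        ib = ref[keep]
        if mad_trim is not None:
            med = np.median(ratios)
            mad = np.median(np.abs(ratios - med))
            if mad > 0:
                inlier = np.abs(ratios - med) <= mad_trim * mad
                ratios, t_sec, ia, ib = ratios[inlier], t_sec[inlier], ia[inlier], ib[inlier]
        mean_ratio = float(ratios.mean())
        total_var = float(ratios.var(ddof=1))
        mean_a = float(ia.mean())
        mean_b = float(ib.mean())
        mean_t = float(t_sec.mean())
        predictor = mean_ratio**2 * (1.0 / (mean_a * mean_t) + 1.0 / (mean_b * mean_t))
        out.append(
            RatioPairStatistics(
                target_mz=float(mz),
                reference_mz=float(panel.reference_mz),
                n_used=ratios.size,
                mean_ratio=mean_ratio,
                total_variance=total_var,
                mean_intensity_a=mean_a,
                mean_intensity_b=mean_b,
                mean_injection_time=mean_t,
                predictor=predictor,
            )
        )
    if not out:
        raise ValueError(
            "no fragment pair had enough co-detected spectra; "
            "check the panel and the matching tolerance"
        )
    return out


def fit_calibration(
    stats: list[RatioPairStatistics], weighted: bool = False
) -> CalibrationFit:
    """Estimate alpha and sigma_o^2 by least squares over fragment pairs.

    One point per pair: x = Poisson predictor, y = total ratio variance.
    Unweighted OLS with a free intercept by default; ``weighted=True``
    weights each pair by its number of retained spectra.
    """
    if len(stats) < 2:
        raise ValueError("need at least 2 fragment pairs to fit a line")
    x = np.asarray([s.predictor for s in stats], dtype=float)
    y = np.asarray([s.total_variance for s in stats], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite predictor or variance in fit input")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all predictors identical")
    X = sm.add_constant(x)
    if weighted:
        model = sm.WLS(y, X, weights=np.asarray([s.n_used for s in stats], dtype=float))
    else:
        model = sm.OLS(y, X)
    with warnings.catch_warnings():
        # 2-point fits have zero residual dof; SE is reported as NaN
        warnings.simplefilter("ignore")
        res = model.fit()
        alpha_se = float(res.bse[1]) if len(stats) > 2 else float("nan")
        sigma0_se = float(res.bse[0]) if len(stats) > 2 else float("nan")
        r2 = float(res.rsquared)
    return CalibrationFit(
        alpha=float(res.params[1]),
        alpha_se=alpha_se,
        sigma0_sq=float(res.params[0]),
        r_squared=r2,
        n_points=len(stats),
        sigma0_se=sigma0_se,
        points=list(stats),
    )


def calibrate_ions(intensity, injection_time, alpha: float = 1.0):
    """Convert reported intensity to an ion count.

    ions = intensity * (injection_time in ms / 1000) / alpha.
    With alpha = 1 this is the uncalibrated ion count I*t.
    Accepts scalars or arrays.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    t = np.asarray(injection_time, dtype=float)
    if np.any(t <= 0):
        raise ValueError("injection time must be positive")
    result = np.asarray(intensity, dtype=float) * (t * 1e-3) / alpha
    if result.ndim == 0:
        return float(result)
    return result
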