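"""Synthetic infusion spectra and DIA elution peaks with ground truth.

Forward model: each fragment accumulates N ~ Poisson(lambda) ions per
fill; the reported intensity is alpha_true * N / t with t the injection
time in seconds (per-second reporting, the convention of beam-type
instruments), optionally degraded by per-fragment multiplicative
Gaussian noise (a non-Poisson floor) and/or common-mode spray noise
shared by all fragments of a spectrum, which cancels in intensity
ratios.

Every draw is a pure function of (seed, spectrum index, fragment index)
via per-spectrum counter-keyed Philox streams, so any sub-range of the
run can be regenerated reproducibly and identical configs give
byte-identical mzML output.

The emission ledger records every true ion count and reported
intensity, making the generators usable as exact oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .msio import SpectrumRecord

__all__ = [
    "SyntheticInfusionConfig",
    "SyntheticDIAConfig",
    "DIAAnalyte",
    "simulate_infusion",
    "simulate_dia_run",
]


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent RNG stream, a pure function of (seed, *key)."""
    ss = np.random.SeedSequence(entropy=(int(seed), *map(int, key)))
    return np.random.Generator(np.random.Philox(ss))


# ---------------------------------------------------------------------------
# Infusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticInfusionConfig:
    """Repeated-fill infusion of one analyte's fragment set.

    mean_ions_per_fill gives the Poisson rate lambda_j (ions per fill)
    for each fragment; extra_noise_cv is the per-fragment multiplicative
    Gaussian CV eta (adds ~ Rbar^2 * 2 * eta^2 to each pair's ratio
    variance without biasing alpha); common_noise_cv is shared across
    all fragments of a spectrum and cancels in ratios.
    """

    n_spectra: int
    fragment_mzs: tuple
    mean_ions_per_fill: tuple
    injection_time: float = 5.0  # milliseconds
    alpha_true: float = 1.0
    extra_noise_cv: float = 0.0
    common_noise_cv: float = 0.0
    mz_jitter_ppm: float = 0.0
    per_fill_reporting: bool = False  # report alpha*N instead of alpha*N/t
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_mzs", tuple(float(m) for m in self.fragment_mzs))
        object.__setattr__(
            self, "mean_ions_per_fill", tuple(float(v) for v in self.mean_ions_per_fill)
        )
        if self.n_spectra < 2:
            raise ValueError("need at least 2 spectra")
        if len(self.fragment_mzs) != len(self.mean_ions_per_fill):
            raise ValueError("fragment_mzs and mean_ions_per_fill lengths differ")
        if any(l <= 0 for l in self.mean_ions_per_fill):
            raise ValueError("mean ion fills must be positive")
        if self.alpha_true <= 0 or self.injection_time <= 0:
            raise ValueError("alpha_true and injection_time must be positive")
        if self.extra_noise_cv < 0 or self.common_noise_cv < 0 or self.mz_jitter_ppm < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def from_json(cls, path) -> "SyntheticInfusionConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def simulate_infusion(
    config: SyntheticInfusionConfig,
) -> tuple[list[SpectrumRecord], pd.DataFrame]:
    """Generate infusion MS2 spectra and the emission ledger.

    Returns
    -------
    spectra : list of SpectrumRecord
        One scan per fill; scans are 1 s apart starting at rt = 0.
    ledger : pd.DataFrame
        Columns scan_index, fragment_mz, n_ions, intensity — the ground
        truth for every emitted centroid (fragments with zero ions emit
        no centroid and appear with intensity 0).
    """
    t_sec = config.injection_time * 1e-3
    mzs = np.asarray(config.fragment_mzs)
    lams = np.asarray(config.mean_ions_per_fill)
    order = np.argsort(mzs)
    spectra: list[SpectrumRecord] = []
    rows = []
    for i in range(config.n_spectra):
        rng = _stream(config.seed, i)
        # fixed draw order: Poisson counts, then per-fragment noise,
        # then common-mode factor, then m/z jitter
        n_ions = rng.poisson(lams)
        intens = config.alpha_true * n_ions.astype(float)
        if not config.per_fill_reporting:
            intens = intens / t_sec
        if config.extra_noise_cv > 0:
            intens = intens * (1.0 + config.extra_noise_cv * rng.standard_normal(mzs.size))
        if config.common_noise_cv > 0:
            intens = intens * (1.0 + config.common_noise_cv * rng.standard_normal())
        intens = np.maximum(intens, 0.0)
        if config.mz_jitter_ppm > 0:
            jitter = rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm, mzs.size)
            obs_mz = mzs * (1.0 + jitter * 1e-6)
        else:
            obs_mz = mzs.copy()
        for j in range(mzs.size):
            rows.append((i, float(mzs[j]), int(n_ions[j]), float(intens[j])))
        keep = intens > 0
        o = order[keep[order]]
        spectra.append(
            SpectrumRecord(
                scan_index=i,
                retention_time=i / 60.0,
                ms_level=2,
                isolation_center=float(np.mean(mzs)),
                isolation_width=2.0,
                injection_time=config.injection_time,
                mz_values=obs_mz[o],
                intensities=intens[o],
            )
        )
    ledger = pd.DataFrame(rows, columns=["scan_index", "fragment_mz", "n_ions", "intensity"])
    return spectra, ledger


# ---------------------------------------------------------------------------
# DIA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DIAAnalyte:
    analyte_id: str
    precursor_mz: float
    fragment_mzs: tuple
    total_ions: float  # expected ions summed over the whole elution peak
    apex_rt: float  # minutes
    peak_fwhm: float  # seconds

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_mzs", tuple(float(m) for m in self.fragment_mzs))
        if self.total_ions <= 0 or self.peak_fwhm <= 0:
            raise ValueError(f"{self.analyte_id}: total_ions and peak_fwhm must be positive")
        if not self.fragment_mzs:
            raise ValueError(f"{self.analyte_id}: empty fragment list")


@dataclass(frozen=True)
class SyntheticDIAConfig:
    """DIA schedule of tiling isolation windows over Gaussian peaks.

    The scan period is injection_time + overhead; the cycle time is one
    full traversal of the windows (n_windows * period). A user-supplied
    cycle_time is validated against that product. ``noise_free=True``
    replaces Poisson draws with their expectations, making every
    downstream ion count an exact function of the config.
    """

    analytes: tuple
    isolation_range: tuple[float, float] = (400.0, 900.0)
    isolation_width: float = 2.0
    injection_time: float = 4.0  # milliseconds
    overhead: float = 1.0  # milliseconds per scan
    cycle_time: float | None = None  # seconds; derived when None
    alpha_true: float = 1.0
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "analytes", tuple(self.analytes))
        lo, hi = self.isolation_range
        if not (hi > lo and self.isolation_width > 0):
            raise ValueError("invalid isolation scheme")
        n_win = self.n_windows
        if not math.isclose(lo + n_win * self.isolation_width, hi, rel_tol=1e-9):
            raise ValueError("isolation windows must tile the precursor range exactly")
        if self.injection_time <= 0 or self.overhead < 0 or self.alpha_true <= 0:
            raise ValueError("invalid timing or gain parameters")
        derived = n_win * (self.injection_time + self.overhead) * 1e-3
        if self.cycle_time is not None and not math.isclose(
            self.cycle_time, derived, rel_tol=1e-9
        ):
            raise ValueError(
                f"cycle_time {self.cycle_time}s inconsistent with "
                f"{n_win} windows x (IT+overhead) = {derived}s"
            )
        for a in self.analytes:
            if not (lo <= a.precursor_mz < hi):
                raise ValueError(
                    f"{a.analyte_id}: precursor {a.precursor_mz} outside "
                    f"isolation range {self.isolation_range}"
                )

    @property
    def n_windows(self) -> int:
        lo, hi = self.isolation_range
        return int(round((hi - lo) / self.isolation_width))

    @property
    def derived_cycle_time(self) -> float:
        return self.n_windows * (self.injection_time + self.overhead) * 1e-3

    @classmethod
    def from_json(cls, path) -> "SyntheticDIAConfig":
        with open(path) as fh:
            cfg = json.load(fh)
        cfg["analytes"] = tuple(DIAAnalyte(**a) for a in cfg["analytes"])
        for k in ("isolation_range",):
            if k in cfg:
                cfg[k] = tuple(cfg[k])
        return cls(**cfg)


@dataclass
class DIALedger:
    """Ground truth of a simulated DIA run."""

    per_scan: pd.DataFrame  # scan_index, analyte_id, rt_min, n_ions, intensity
    per_analyte: pd.DataFrame  # analyte_id, total_n_ions, sum_intensity_x_t


def simulate_dia_run(
    config: SyntheticDIAConfig,
) -> tuple[list[SpectrumRecord], DIALedger]:
    """Generate a DIA run over the configured window schedule.

    Each analyte is sampled once per cycle by the window containing its
    precursor (half-open on the upper edge). The expected ions in a
    scan are the analyte's total_ions times the Gaussian elution-profile
    mass falling in that cycle's interval, split equally over its
    fragments; reported fragment intensity is alpha_true * N / t.
    """
    lo, _ = config.isolation_range
    n_win = config.n_windows
    period = (config.injection_time + config.overhead) * 1e-3  # seconds
    cycle = config.derived_cycle_time
    t_sec = config.injection_time * 1e-3

    sigmas = np.asarray([a.peak_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
                         for a in config.analytes])
    apexes = np.asarray([a.apex_rt * 60.0 for a in config.analytes])  # seconds
    t_start = max(0.0, float(np.min(apexes - 5.0 * sigmas)))
    t_end = float(np.max(apexes + 5.0 * sigmas))
    n_cycles = max(2, int(math.ceil((t_end - t_start) / cycle)) + 1)

    window_of = {}
    for k, analyte in enumerate(config.analytes):
        window_of.setdefault(int((analyte.precursor_mz - lo) // config.isolation_width),
                             []).append(k)

    spectra: list[SpectrumRecord] = []
    scan_rows = []
    scan_index = 0
    for c in range(n_cycles):
        for w in range(n_win):
            t = t_start + c * cycle + w * period  # scan start, seconds
            center = lo + (w + 0.5) * config.isolation_width
            mz_acc: list[float] = []
            int_acc: list[float] = []
            for k in window_of.get(w, ()):
                analyte = config.analytes[k]
                # Gaussian profile mass in this cycle's sampling interval
                z_hi = (t + cycle / 2.0 - apexes[k]) / sigmas[k]
                z_lo = (t - cycle / 2.0 - apexes[k]) / sigmas[k]
                lam = analyte.total_ions * (norm.cdf(z_hi) - norm.cdf(z_lo))
                n_frag = len(analyte.fragment_mzs)
                if config.noise_free:
                    counts = np.full(n_frag, lam / n_frag)
                else:
                    rng = _stream(config.seed, scan_index, k)
                    counts = rng.poisson(lam / n_frag, n_frag).astype(float)
                intens = config.alpha_true * counts / t_sec
                total_n = float(counts.sum())
                if total_n > 0:
                    mz_acc.extend(analyte.fragment_mzs)
                    int_acc.extend(intens)
                scan_rows.append(
                    (scan_index, analyte.analyte_id, t / 60.0, total_n,
                     float(intens.sum()))
                )
            mz_arr = np.asarray(mz_acc)
            int_arr = np.asarray(int_acc)
            if mz_arr.size:
                o = np.argsort(mz_arr, kind="stable")
                mz_arr, int_arr = mz_arr[o], int_arr[o]
                # co-isolated analytes sharing a fragment m/z merge into
                # one centroid
                uniq, inverse = np.unique(mz_arr, return_inverse=True)
                if uniq.size < mz_arr.size:
                    int_arr = np.bincount(inverse, weights=int_arr)
                    mz_arr = uniq
                keep = int_arr > 0
                mz_arr, int_arr = mz_arr[keep], int_arr[keep]
            spectra.append(
                SpectrumRecord(
                    scan_index=scan_index,
                    retention_time=t / 60.0,
                    ms_level=2,
                    isolation_center=center,
                    isolation_width=config.isolation_width,
                    injection_time=config.injection_time,
                    mz_values=mz_arr,
                    intensities=int_arr,
                )
            )
            scan_index += 1
    per_scan = pd.DataFrame(
        scan_rows, columns=["scan_index", "analyte_id", "rt_min", "n_ions", "intensity"]
    )
    per_analyte = (
        per_scan.assign(ions_from_it=per_scan["intensity"] * t_sec)
        .groupby("analyte_id", sort=True)
        .agg(total_n_ions=("n_ions", "sum"), sum_intensity_x_t=("ions_from_it", "sum"))
        .reset_index()
    )
    return spectra, DIALedger(per_scan=per_scan, per_analyte=per_analyte)
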