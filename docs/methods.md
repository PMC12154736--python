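# Methods

## Model and estimation procedure

A fragment's reported intensity is modeled as I = α·N/t: N ions accumulated
over injection time t (seconds), scaled by an instrument response factor α.
Repeated MS2 spectra of a stable infused calibrant give, for each fragment
pair (target a, reference b), a series of intensity ratios R = I_a/I_b in
which α, t and common-mode spray fluctuations cancel. Poisson counting
(σ²_N = N) propagated to the ratio yields

σ²_T = α·R̄²(1/(Ī_a·t̄) + 1/(Ī_b·t̄)) + σ²ₒ,

a line in x = R̄²(1/(Ī_a t̄) + 1/(Ī_b t̄)) whose slope is α and whose
intercept σ²ₒ collects ratio variance not explained by counting statistics.
One point per fragment pair is formed from *per-pair means* (mean ratio,
mean intensities, mean injection time over the retained spectra); per-spectrum
predictors are never averaged. Only spectra in which both fragments were
detected (intensity > 0) enter a pair; pairs retained in fewer than
`min_spectra` spectra (default 100, below which a variance-of-variance is
too unstable to regress on) are dropped with a warning. The fit is
unweighted OLS with a free intercept (a weighted variant, weights ∝ n_used,
sits behind a flag); the slope standard error and R² are the ordinary OLS
quantities. With exactly two points the fit is returned but its standard
errors are reported as NaN. No outlier rejection is applied by default; an
optional MAD-based ratio trim exists behind a flag.

Assumptions: the two fragments of a pair are measured in the same spectrum
under identical α and t; ion counts are independent Poisson; the analyte
supply is stable over the run (drift shared by both fragments cancels in
the ratio; differential drift does not and inflates σ²ₒ).

### Conventions

- Ratio orientation is R = I_target / I_reference. The predictor is
  symmetric in the pair, so orientation only relabels R̄; fixed for
  reproducibility.
- Sample variance uses the n−1 denominator.
- Injection time is carried in milliseconds (as mzML stores it) and
  converted to seconds exactly where ions = I·t is formed, so ions/sec × s
  gives ions and α ≈ 1 corresponds to intensities that are true ions/sec.
- `calibrate_ions(I, t_ms, alpha)` returns I·(t/1000)/α; α = 1 gives the
  uncalibrated ion estimate.
- One panel (one calibrant compound) per fit; separate compounds are fitted
  separately rather than pooled.

## Ion-count metrics for DIA peaks

From a per-analyte chromatogram (the spectra whose isolation window
contains the precursor, summed over the analyte's transitions) and a peak
boundary, with t in seconds and all counts divided by α:

- apex = the in-boundary scan with the highest summed transition intensity
  (ties → earliest retention time; the apex is confined to the boundary so
  an interference outside it cannot capture it);
- apex total ion count = TIC(apex)·t(apex)/α — mirrors the ion count the
  instrument reports for that scan;
- LC peak analyte ion count = Σ over in-boundary scans of summed transition
  intensity × t / α — the ions contributing to the analyte's quantification;
- apex analyte ion count, LC peak total ion count and the LC peak TIC area
  (trapezoidal integral of TIC over retention time, in intensity·minutes,
  neither α- nor t-corrected) are constructed by direct analogy with the
  two definitions above; their exact report-grid formulas were not
  published, so these three are *reconstructed* definitions.
- Boundary membership is a closed retention-time interval; isolation-window
  membership is half-open on the upper edge so adjacent non-staggered
  windows partition the precursor axis.
- TIC is the recomputed sum of centroid intensities by default; the
  vendor-reported TIC cvParam is available behind a flag. The apex metric
  matches the raw-file ion count only when the same TIC convention is used.
- Protein-level roll-up = sum of LC peak analyte ion counts over the
  protein's peptides.

## Timing and precision metrics

- Acquisition rate = spectrum count / retention-time span (Hz).
- Overhead = mean scan-to-scan period − set injection time (ms). The
  scan-to-scan period is used because per-scan duration metadata is not
  reliably present in mzML.
- Cycle time = median gap between successive occurrences of the lowest-m/z
  isolation window in the precursor range; the median resists dropped scans.
- CV table: CV = 100·sd/mean per analyte on the linear scale (sd with n−1),
  analytes with <2 non-missing replicates or zero mean skipped and counted.
  Median normalization divides each replicate column by its median and
  multiplies by the grand median (median of all non-missing values), keeping
  normalized values on the original scale.
- Distribution mode: histogram of log10(values) with Freedman–Diaconis bin
  width; mode = 10^(center of the highest-count bin), ties resolved to the
  lower bin. Deterministic by construction; a Gaussian-KDE peak is available
  behind a flag. The estimate is only resolved to one bin width, and near a
  flat density peak the argmax bin can wander a few bins under sampling
  noise.
- Pairwise comparison: log2 of the ratio of per-analyte mean abundances
  (B over A) across the analytes present in both tables with positive means.

## The simulator

`simulate_infusion` emulates repeated fills of a calibrant: per spectrum
and fragment, N ~ Poisson(λ_j), reported intensity α_true·N/t (per-second
reporting; a per-fill mode emulating trap-style units exists), optional
per-fragment multiplicative Gaussian noise of CV η, optional common-mode
noise shared by all fragments of a spectrum, and uniform m/z jitter in ppm.
`simulate_dia_run` schedules isolation windows that tile the precursor
range at a scan period of injection time + overhead and emits Gaussian
elution peaks: the expected ions per scan are the analyte's total ions
times the profile mass in that cycle's interval, Poisson-drawn (or taken
exactly in noise-free mode) and split equally over the analyte's fragments.
Every draw is logged to a ledger (per-scan N and I, per-analyte Σ I·t), so
downstream extraction and metrics can be checked for exact conservation.
All randomness is keyed as a pure function of (seed, spectrum index,
fragment/analyte index) through counter-based Philox streams: identical
configs give byte-identical mzML.

Default study conditions for calibration checks: 5000 spectra, 8 fragments
with mean fills between 500 and 20,000 ions, 5 ms injection time — a
realistic infusion experiment (thousands of repeated MS2 scans of one
precursor, fragment abundances spanning ~1.5 decades around a typical AGC
target). At these settings the fitted α has a seed-to-seed spread of about
2.4% (so recovery within 5% in roughly 19 of 20 runs), and the acceptance
check completes in seconds on one CPU.

What the simulator does **not** emulate: isotope envelopes, charge states,
chimeric fragmentation, retention-time drift, AGC feedback (injection time
is fixed, not adapted to ion flux), detector saturation, and
intensity-dependent m/z calibration error. Passing tests therefore
demonstrate the correctness of the estimators under the stated statistical
model, not robustness to every artifact of real acquisitions.

### A caveat on the noise floor

Per-fragment multiplicative noise adds ≈ R̄²·2η² to a pair's ratio
variance. That term is constant across pairs — i.e. acts as the intercept
σ²ₒ — only when R̄ is comparable across pairs. With a single shared
reference and widely varying fragment abundances, R̄² co-varies with the
predictor and part of the noise loads onto the slope instead. The tests
therefore verify the pair-level formula by Monte Carlo, and probe
regression-level floor recovery with matched-abundance pairs (R̄ = 1).
Practically: a fitted intercept near zero (as observed on well-behaved
instruments) is evidence that η is small, in which case the bias on α is
negligible.

## Numerical and degenerate-input choices

- mzML: reading accepts plain or indexed files, 32/64-bit float arrays,
  zlib or no compression; scan start times in seconds or minutes are
  normalized to minutes. Spectra missing ion injection time are rejected
  (the calibration is undefined without t), as are profile-mode spectra
  (centroiding is out of scope). Writing emits uncompressed 64-bit floats
  and no timestamps, so round trips are exact and outputs byte-stable.
- Fragment matching takes the most intense centroid within ±tolerance
  (default 10 ppm; 0.3 m/z absolute suits ion-trap data), not the nearest
  m/z: robust to small calibration jitter around a prominent fragment.
  Panels whose targets are closer than twice the tolerance are rejected as
  ambiguous.
- A fit on an all-zero response returns slope and intercept 0 with R²
  reported as NaN; identical predictors across all pairs are a fatal
  degenerate design.

## Limitations

- α is assumed m/z-independent within a panel; compound-to-compound
  differences are visible as between-panel spread, not modeled.
- Boundaries are inputs: no peak detection or boundary refinement.
- The OLS slope standard error understates the seed-to-seed variability of
  α̂ somewhat, because regression points share the reference fragment and
  are therefore weakly correlated.
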