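# Methods

This note records the models, conventions and numerical choices behind
`mxpquant`, and what the simulation-based tests do and do not demonstrate.

## Mass arithmetic

Fatty acyl species are identified as `FA <carbons>:<double_bonds>` with an
optional derivatization suffix. The neutral formula ladder is

    FREE    C_n H_(2n-2·db) O2
    -OOH    FREE + O2
    -OOMxP  -OOH + C4H8O

where the C4H8O step is the 2-methoxypropene addition across the
hydroperoxide (forming the perketal -OO-C(CH3)2-OCH3). Hydroperoxidation
requires at least one double bond (the -OOH group is allylic to a C=C), so
`FA 18:0-OOH` is rejected at the type level; the double-bond count is also
capped at `(carbons − 2)/2` (truncated).

Monoisotopic masses are pinned: C 12.000000, H 1.00782503, O 15.99491462,
Na 22.98976928, electron 0.00054858 Da. Adduct deltas include the electron
([M−H]⁻ = −H + e⁻; [M+Na]⁺ = +Na − e⁻); without the electron term the
reference exact masses (313.2384, 409.2924) are missed in the fourth
decimal. Only singly charged adducts are supported — the assay uses no
others. m/z values are reported at 4 decimals in the exact-mass context
and 1 decimal in the SRM context, rounding ties away from zero (the
convention of instrument transition tables; Python's built-in banker's
rounding would give different last digits).

## Transitions

The shipped registry holds the eight instrument-optimized channels
(precursor and product m/z, collision energy, tube lens; FA 19:1-OOMxP
flagged as internal standard). Registry values are authoritative for
acquisition and matching; theory is advisory QC, because tuned precursor
m/z deviate from the computed sodiated masses by up to ~0.13 Da
(e.g. FA 20:4-OOMxP prints 431.4 where theory gives 431.3).

Product ions follow two neutral-loss rules: species with db ≥ 2 lose the
MxP unit, nominally 72.0 Da; monounsaturated species show an empirical
202.1 Da loss. The 202.1 Da constant is fixed from the registry's three
monounsaturated parent−product differences (201.9, 202.1, 202.1 — we pin
the modal 202.1, which also reproduces the printed product ions when
applied to the printed parents); the underlying fragment chemistry is not
characterized and we deliberately do not guess it. The default QC
tolerance of 0.2 Da covers the largest known print-vs-theory gap while
still rejecting neighboring species (minimum inter-species precursor
spacing in the registry is 2.0 Da).

## Simulator

`simulate` generates per-channel traces

    y(t) = baseline + drift·t + amplitude·shape(t; RT, σ, τ) + N(0, noise_sd),
    amplitude = concentration · response_factor · matrix_multiplier,

with a Gaussian or exponentially modified Gaussian shape normalized to
unit apex, intensities clipped at zero. Replicate variation is a
unit-mean lognormal multiplier on the amplitude (keeps intensities
positive; its σ is chosen so the multiplier's CV equals `replicate_cv`).
Every scenario must carry an integer seed; per-trace substreams are
derived from (seed, stream, species index) so traces are reproducible
regardless of generation order.

Defaults encode the validated assay's conditions: a 6-min run sampled at
5 points/s (dwell/sampling rates are not published for the assay; 5/s is
a typical SRM cycle rate and is configurable), retention times evenly
spaced 1.5–5.5 min in registry order (the published chromatograms show the
elution order but not the times), calibration levels 0.01, 0.1, 1, 2.5,
5, 7.5, 10, 25, 50, 100 pmol/µL with a constant internal standard of
10 pmol/µL in the final extract (10 µL of 100 µM IS made up to 100 µL), a
50 pmol/µL validation spike, matrix multipliers of 1.02 and 1.20 for the
FA 18:1 and FA 22:1 derivatives (the two enhancement cases) and 0.91
elsewhere (the published suppression value for the IS), and an extraction
recovery fraction of 0.70. Default analyte response factor is 2000
counts·(pmol/µL)⁻¹ apex height with noise sd 50, which places LOD at
0.1 pmol/µL and LOQ near 1 pmol/µL — the sensitive end of the assay's
published range.

A ground-truth ledger (concentrations, response factors, multipliers,
seed) is emitted next to every sample set. Estimators never read it; it
exists so tests can compare estimates against generative truth.

What the simulator does **not** emulate: co-elution and interference,
retention-time drift between batches, detector saturation, carryover,
heteroscedastic (signal-proportional) noise, and isomeric -OOH species.
Passing parameter-recovery tests therefore demonstrate the correctness of
the estimators under the stated noise model, not assay performance on
real instrument data.

## Peak processing

The baseline is the straight line through the median intensity of the
five points just outside each edge of the retention-time window, which
removes a linear drift exactly. The apex is located on a smoothed,
baseline-subtracted signal (moving average, default window 5; a
Savitzky–Golay option exists) and then pinned to the raw maximum inside
the peak boundaries, so the reported apex matches an exhaustive raw-signal
scan. Boundaries walk out from the smoothed apex to the first local
minimum or to where the signal falls to 1 % of the apex height; the 1 %
cut keeps 99.8 % of a Gaussian's area, so noise-free areas agree with
A·σ·√(2π) within 1 % (a 5 % cut, sometimes used, loses ~1.4 % of the
area). Integration runs on the raw, unsmoothed signal (unbiased areas);
areas are intensity·seconds.

Noise is 1.4826 × the median absolute deviation of the baseline-subtracted
signal outside the peak — robust to residual peak tails. The published
method does not define its noise estimator (instrument software defaults
were presumably used); ours is a documented choice, so simulated LOD/LOQ
values are internally consistent rather than instrument-exact. S/N =
height/noise, capped at 10⁶ with a `zero_noise` QC flag for effectively
noise-free traces. Detection requires S/N ≥ 3; quantifiability S/N ≥ 10.
One caveat found during development: when the baseline level is far below
the noise sd, zero-clipping concentrates probability mass at a single
intensity value and the MAD collapses; physically the baseline offset
always exceeds the noise, and scenarios should respect that.

The default retention-time window is ±0.3 min around the expected RT
(peaks are baseline-resolved in a 6-min run); configurable per species.

## Quantitation

Calibration responses default to the area ratio to the internal standard
(`area_ratio_to_IS`); absolute areas are available. Whether the published
slopes are ratio-scale or absolute is not stated; ratio-scale is the
standard practice when a constant IS is spiked, and is our default. The
line is fitted by OLS (statsmodels) over the levels at or above the LOQ;
sub-LOQ levels are excluded from the fit but still determine LOD/LOQ.
LOD/LOQ snap to prepared grid levels with no S/N interpolation — limits
are only claimed at concentrations actually prepared. At least four
usable levels are required; a non-positive fitted slope is rejected.

Samples are quantified only if the internal-standard peak passes S/N ≥ 10;
otherwise the whole sample fails QC and no concentrations are emitted.
Analytes below S/N 3 report "ND"; between 3 and 10 or below the LOQ,
"<LOQ" (the value is still reported, flagged, rather than suppressed —
survey-style reporting needs graded flags); outside the fitted range,
"extrapolated". Concentrations are pmol/µL of final extract, with an
optional dilution-chain back-calculation (default 100 µL final from 50 µL
source, ×1000 for per-mL reporting).

Recovery and matrix effect are paired replicate ratios reported as
mean ± sd. CVs are 100·sd/mean (sd with n−1); the inter-day CV is the CV
of daily means over ≥ 3 days. Group statistics (ANOVA and multiple
comparisons) are out of scope — the reports are tidy tables for external
statistics tools.

## Test problem sizes

Property and recovery tests run on single-analyte scenarios (6-min traces
at 5 points/s ≈ 1800 points; 3-min runs for Monte-Carlo-heavy checks),
with 100 traces for detector-oracle and CV-band checks, 5 seeds per rung
on a 5-rung noise ladder for LOD/LOQ monotonicity, and n = 5–8 replicates
for recovery/matrix checks. These sizes give stable statistics for the
stated tolerances while keeping the whole suite fast.

## Known limitations

* Positional (regio-)isomers of the -OOH group are not modeled — the
  assay itself cannot distinguish them.
* Only one -OOH per acyl chain; multiply oxidized species are out of
  scope.
* The 202.1 Da monounsaturated loss is an empirical constant, not a
  mechanistic prediction.
* mzML support covers SRM chromatogram lists (32/64-bit float arrays,
  optional zlib compression); spectra, vendor raw files and indexed
  wrappers are not read.
* Overlapping-peak deconvolution and cross-batch retention alignment are
  not implemented.
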