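# Methods

## Pipeline

The analysis chain is fixed: resample → band-pass → epoch → reject →
cross-spectra → band coherence → TotCoh → group statistics → figures.

**Conditioning.** Recordings are polyphase-resampled to the analysis rate
(default 512 Hz) and band-pass filtered 0.2–47 Hz with a zero-phase
windowed-sinc FIR (Hamming window, ~53 dB stopband; the kernel length is
set by the 0.2 Hz edge, ≈16.5 s at 512 Hz, and the symmetric kernel is
applied once by centred FFT convolution, which is exactly zero-phase).
The signal is cut into consecutive non-overlapping 2-s epochs (trailing
partial epoch discarded). An epoch is rejected when any sample exceeds
100 µV in magnitude or when a channel's epoch **log**-variance lies more
than 5 robust z-units (median/MAD) above that channel's across-epoch
distribution; raw epoch variances of band-limited signals are strongly
right-skewed, and the log restores the calibration of the z-threshold
(measured: zero false flags on clean synthetic EEG vs several per subject
on raw variances). At least 180 s of clean data must survive or the
subject errors out. The rejection stage is deterministic; an external
decomposition (e.g. an ICA run elsewhere) can be applied through
`reject_epochs`, which drops explicitly listed epoch indices. Recordings
are analysed as referenced; no re-referencing is applied.

**Spectra.** One Welch segment per 2-s epoch (epochs are already
disjoint): per-epoch demeaning, Hann taper, FFT, epoch-averaged cross- and
auto-spectra with density normalisation (the auto-spectrum integrates to
the signal variance). Resolution is 0.5 Hz. MSCoh = |G_xy|²/(G_xx·G_yy);
frequencies where an auto-spectrum falls below 10⁻³⁰ µV²/Hz raise rather
than clamp. Band values are unweighted means over bins with
lo ≤ f < hi (half-open, so adjacent bands never share a bin; the top edge
of the final band is inclusive). With K averaged epochs the coherence of
independent signals has an estimator floor ≈ 1/K, so a minimum of two
epochs is enforced and group comparisons should use comparable K.

**TotCoh.** Per-electrode mean coherence averaged over electrodes; by
symmetry this equals the mean over unordered pairs, which is how it is
computed. ROI TotCoh averages within-ROI pairs only and is strict about
ROI electrodes missing from the matrix. Electrodes outside every ROI (the
64-channel montage's AFz, FT9, FT10) enter the global value and maps but
no ROI.

**Statistics.** Median split: amplitudes strictly below the sample median
→ L-MEP, ties at the median → H-MEP (with two subjects tied at the median
of 87, this reproduces a 42/45 split, the only assignment consistent with
the reference cohort). Pair maps: pooled two-sample t per electrode pair,
BH-FDR with one family per band (per-band families are what produce
distinct per-band adjusted thresholds); the reported `p_FDR` is the
largest rejected raw p (0 when none). The TotCoh ANOVA is the univariate
mixed model — Group between; ROI, Band within — computed by exact
orthogonal stratum decomposition (subject means; per-subject ROI, Band and
ROI×Band deviations), each within effect tested against its own
subject-interaction stratum: df(Group×ROI) = (g−1)(r−1) over (N−g)(r−1),
i.e. (4, 340) for N=87, g=2, r=5. Group sizes may be unbalanced; the
within-subject grid must be complete. No sphericity correction is applied
(a limitation, documented). Duncan's multiple range test runs on the
Group×ROI×Band cell means with the Group×ROI stratum's error mean square
and df: ordered means, critical range q*(p, df; 1−(1−α)^(p−1))·√(MSE/n)
(harmonic n across the span), widest-first step-down with the containment
rule — a pair inside a retained homogeneous span is never declared
different. The error-stratum choice for the interaction post hoc is a
design decision of this package; published reports of this design rarely
state theirs, and printed post hoc p-values cannot disambiguate it.
Nominal per-pair p-values invert the protection level through the
studentized-range survival function and can be disabled
(`nominal_p=False`) in simulation loops where only decisions matter.

## Synthetic cohorts

Each band of the scheme may carry shared unit-variance Gaussian sources,
synthesised in the frequency domain (complex-Gaussian coefficients on the
rfft bins inside [lo, hi), zero elsewhere) so their spectra are exactly
flat in band. Channel noise is the sum of independent band-limited
components — one per scheme band plus filler segments below 2 Hz and up
to 64 Hz — with variances following a 1/f^α envelope (α = 1, total
100 µV² per channel by default) plus a small broadband sensor floor
(0.05 µV²). Because source and noise are both flat inside a band, the
band coherence of a channel pair has the closed form

    γ²_ij = (Σ_k w_ik w_jk)² / ((Σ_k w²_ik + ν_i)(Σ_k w²_jk + ν_j))

with ν the in-band noise variance (`SyntheticSpec.inband_noise_variance`),
and `weight_for_coherence` inverts the symmetric two-channel case. Group
effects are additive weight increments applied to H-MEP subjects; the
default baseline is a posterior alpha coupling (γ² 0.4 / 0.3 in Alpha 1/2)
plus a weaker central Beta 1 coupling (0.2), a stylised eyes-closed
resting pattern. Optional artifact segments add ±300 µV smooth frontal
excursions on a 2-s grid, recorded in recording metadata.

MEP trials are baseline EMG noise plus one biphasic deflection inside the
15–50 ms response window whose peak-to-peak amplitude is log-normal:
subject locations N(−0.75, 0.20²) for L-MEP and N(0.33, 0.30²) for H-MEP
on the log scale (≈0.49 vs ≈1.4 mV means), trial scatter σ = 0.15. The
separation is chosen so that a median split on measured amplitudes
reproduces the intended group labels in ≥95% of subjects — the generator's
contract; real cohorts show heavier overlap between their printed group
distributions, which would make "intended" labels ill-defined. Covariates
are drawn group-matched (equal age/sex/education distributions up to the
reference cohort's small printed differences; cMMSE shifted ≈0.5 points;
grip unshifted).

Everything is reproducible bit-for-bit from (spec, seed); per-subject
streams are derived as `default_rng([seed, tag, subject])`.

### What the generator does not emulate

No head-volume conduction (planted couplings are network-level, not
dipole-level), no nonstationarity or phase-amplitude coupling, no
subject-level heterogeneity in true coherence (between-subject variance in
estimates is estimation noise plus group structure), and noise magnitudes
are calibrated for effect detectability at realistic group sizes rather
than to any real cohort's variance. Passing tests therefore demonstrate
correctness of the estimators and inference under the stated model, not
performance on real recordings.

## Numerical choices and known behaviour

- **Band-edge leakage bias.** Hann leakage mixes out-of-band noise into
  the edge bins of each band. For bands ≥8 bins wide the band-averaged
  coherence stays within ~0.03 of truth; the 4-bin Alpha 2 band is biased
  low by up to ~0.07 at γ² = 0.5 (2 of its 4 bins are edge bins). The bias
  is group-symmetric, so group contrasts lose a little effect size but
  gain no spurious structure. Estimator-recovery checks therefore use
  wide bands; the Alpha 2 smearing is asserted at its measured magnitude.
- **Filter ringing.** The 16.5-s high-pass kernel spreads large artifacts
  into neighbouring epochs; rejection correctly flags those neighbours.
- **Tie-breaks.** Median ties → H-MEP; FDR threshold 0 when no rejection;
  stable sorts throughout.
- **Determinism.** Results bundles are pure functions of (config, seed,
  input); figures scrub volatile metadata so identical inputs give
  byte-identical files.
- **Degenerate inputs.** Zero-variance test inputs, single channels,
  single epochs, empty bands, missing ROI electrodes and incomplete ANOVA
  grids all raise with specific messages rather than propagating NaNs.

## Problem sizes

The default configuration mirrors a realistic acquisition (64 channels,
1000 Hz, 5 min, 87 subjects). Simulation suites (null error control,
planted-effect power) run the identical pipeline on the reduced 19-channel
montage at 128 Hz with 200-s recordings and 40 subjects per group: epoch
count (100), 0.5-Hz resolution, band scheme and group sizes are unchanged,
so every statistical property under test is preserved while repeated
cohorts run in seconds. `scripts/acceptance.py` uses 10-replicate
null/power runs; the test suite uses 50 and 20.

## Limitations

Sensor-space coherence is volume-conduction-sensitive; no imaginary
coherency or leakage correction is provided (out of scope by design). The
ANOVA applies no sphericity correction. Duncan's procedure does not
control the family-wise error rate at α (by construction of its
protection levels). EDF support covers continuous recordings with a
uniform rate; BrainVision/FIF containers are out of scope.
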