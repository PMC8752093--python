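# Methods

## Scope and model

fcslab implements the analysis chain of a two-color confocal FCS
experiment — from binned photon-count traces to diffusion coefficients,
molar concentrations and condition-level statistics — together with a
Brownian-dynamics generator of synthetic traces, so that every stage can be
validated against known ground truth without instrument data.

The physical model is the standard one for point FCS: fluorescent
particles diffuse freely in 3D, the detection efficiency is a 3D-Gaussian
molecular detection function (MDF)

    MDF(r) = exp(-2 (x^2 + y^2) / w_xy^2 - 2 z^2 / w_z^2),

and the normalized fluctuation autocorrelation of one freely diffusing
species is

    G(tau) = offset + (1/N) (1 + tau/tau_D)^-1 (1 + tau/(kappa^2 tau_D))^-1/2,

with mean occupancy `N`, diffusion time `tau_D = w_xy^2 / 4D`, and
structure parameter `kappa = w_z/w_xy`.  The effective volume is
`V_eff = pi^1.5 w_xy^2 w_z`, so `c = N / (N_A V_eff)`.  Cross-correlation
between the two color channels reports co-diffusion: its short-lag
amplitude is zero (within error) for independently diffusing species and
grows with the dual-labeled fraction.

## Synthetic-data generator

* **Geometry.** Default waist `w_xy = 0.25 um`, `kappa = 5`
  (`V_eff = 0.435 fL`, the right order for a confocal volume of ~1 fL).
  Both are configuration fields, never hard-coded downstream.
* **Box.** Periodic cuboid with half-widths `box_factor * (w_xy, w_xy, w_z)`
  (minimum 5, so the MDF at the boundary is < 1e-21 of its peak).  The
  particle number of each species is drawn per realization from a Poisson
  law with mean `c N_A V_box` (grand-canonical), which is what makes the
  amplitude law `G(0) = 1/(c N_A V_eff)` hold exactly for an open volume.
* **Propagation.** Isotropic Gaussian steps with per-axis variance
  `2 D dt`.  Full-scale defaults are `dt = 1 us`, 2 us bins and 120 s
  duration, matching per-cell live acquisitions; for a diffusion time of
  ~1 ms this is >= 200 steps per tau_D and a discretization bias on tau_D
  below 1%.
* **Detection.** Expected counts per bin are the per-step sum of
  brightness x MDF x dt plus uncorrelated background; realized counts are
  Poisson.  The detector is ideal (no afterpulsing, dead time, or triplet
  blinking) — the fitted model function assumes the same.
* **Photobleaching** is first-order stochastic dark conversion: each
  particle receives an exponential lifetime with rate `bleach_rate`, so
  the mean fluorescent number decays as `N0 exp(-k t)`.  A deterministic
  per-particle *brightness* decay was considered and rejected: the
  square-root detrending transform (below) preserves the correlation
  amplitude exactly under number decay, but under brightness decay at
  constant N it leaves a residual amplitude attenuation equal to the
  time-average of the decay (verified numerically: fitted N inflated by
  1/<f> = 1.42 at k T = 0.75).  Since the point of the corrector is to
  recover the unbleached N, the generator and corrector must agree on
  what bleaching is, and dark conversion is both the physically usual
  reading and the one the corrector is built for.
* **Determinism.** One SFC64 generator per trace, seeded from the config;
  identical configs give bit-identical traces.  Gaussian increments are
  produced from float32 uniform blocks via Acklam's inverse-CDF rational
  approximation (relative error ~1e-9) fused into the numba propagation
  kernel; uniforms are floored at 1e-12 to keep the transform finite.
  Chunks of 256 steps bound memory at a few MB per thousand particles.

## Correlator

`correlate_direct` evaluates every integer lag with the *symmetric*
normalization (channel means taken over the overlapping segments); it is
the brute-force reference.  `correlate_multitau` uses the standard
multi-tau layout: `m = 16` linear lags at level 0, then 8 new lags per
octave with counts rebinned x2 between levels, identical arithmetic to the
direct estimator at level 0.  Levels are dropped (with a warning) once the
rebinned trace holds fewer than 16 bins per lag.  Per-lag errors are the
standard error over 10 contiguous trace blocks.

Two known estimator properties matter for fitting:

* the finite-trace normalization bias, approximately
  `-2 G(0) tau_int / T`, appears as a small negative baseline at long
  lags; the fit therefore floats a baseline offset by default, and the
  lag grid deliberately reaches tens of diffusion times so that the
  offset is identified by the tail rather than traded against tau_D;
* estimates at lags much shorter than tau_D share the same slow occupancy
  noise, so `zero_lag_amplitude` reports an error that assumes fully
  correlated short-lag noise (no 1/sqrt(n) shrink).

## Bleach detrend and background correction

The per-channel mean intensity is rebinned to ~1 s resolution (1/20 of
the trace for short traces), fitted with `F0 exp(-t/tau_b)`, and flagged
negligible when the implied decay over the trace is < 2%.  Detrending
applies `F_c = F/sqrt(f) + F0 (1 - sqrt(f)) dt`, which restores a
stationary mean and, under number bleaching, preserves the correlation
amplitude to first order.  Non-convergent bleach fits fall back to the
negligible model with a warning rather than failing the cell.

Uncorrelated background `B` attenuates the amplitude by `((F-B)/F)^2`;
fitted occupancies are corrected by that factor, with `F <= B` treated as
an unusable channel.  `B` is an ensemble-median scalar per channel and
compartment supplied through configuration (in the lab it comes from
untagged cells); the pipeline never estimates it from the analyte trace.

## Fitting and calibration

Weighted least squares (lmfit/Levenberg-Marquardt) with weights
`1/G_err^2`; initial guesses `N0 = 1/max(G)` and tau_D at the half-height
lag; bounds `N in [1e-3, 1e6]`, `tau_D in [first lag, T/10]`; lags below
5 base bins are excluded to suppress shot-noise artifacts.  kappa is fixed
from calibration — kappa and tau_D are poorly identifiable jointly on
single-cell curves.  Only the single-component model is provided; shifts
in D are interpreted through complex size, not mixtures.  Non-convergence
and non-positive amplitudes return `converged=False`, never defaults.

Calibration measures a reference dye of known `D_ref` per channel:
`w_xy = sqrt(4 D_ref tau_D_ref)` and `V_eff` follow, each channel
separately because chromatic volume mismatch is real.  Because every
analyte D and c scales with the calibrated waist, the dye measurement is
designed for precision the way real calibrations are: a dilute (5 nM)
sample for a large correlation amplitude, high molecular brightness
(250 kHz; a free dye at elevated excitation, so several photons per
transit), several repeat traces whose curves are averaged pointwise
before a single fit, and a fit window capped at 50 expected diffusion
times so the floated baseline cannot trade against tau_D in the
noise-dominated tail.  With the defaults the calibrated tau_ref carries a
~2% standard error.  Reference D values are user-supplied; any
temperature correction between dye literature values and live-cell
conditions is the caller's explicit choice.

## Ensemble statistics

Per-cell (D, c) values are grouped by condition, compartment and channel;
medians with MAD and IQR are reported (published spreads are often
unlabeled, so both robust dispersions are emitted, neither privileged).
Pairwise comparisons use the two-sided Mann-Whitney U test — exact null
enumeration for tie-free problems with `n_a n_b <= 1e4`, otherwise the
normal approximation with tie and continuity corrections — with stars at
p < 0.001 / 0.01 / 0.05.  p-values are unadjusted across condition pairs
by design.  Directionality is left to interpretation: a one-sided test
would presuppose the conclusion.

## Desk-scale study sizes

The generator's full-scale defaults describe the real experiment; the
test suite and the acceptance script run the same physics at sizes chosen
once for a single CPU: 0.2–1.5 s traces at 20 us bins and steps (>= 45
steps per diffusion time for the slowest species studied), `box_factor 5`
(~3,500 particles at 75 nM), 30–45 synthetic cells per ensemble, and
0.3–0.4 s dye traces at 1–2 us bins.  At these sizes the per-cell scatter
of fitted tau_D is 15–25% and of N about 10%, so ensemble medians are
determined to a few percent — comfortably inside the 10% recovery bounds
the tests assert.  Repetition-heavy statistical checks (type-I error,
detection power) draw per-cell values from a lognormal cell-scatter model
(`sample_cell_values`, median-exact parameterization
`sigma = ln(1 + spread/median)`) instead of re-running the full physics
hundreds of times; they validate the statistics module, while single
ensembles validate the physics pipeline.

What passing these tests shows: the estimators and corrections are
unbiased at the few-percent level under the model's own assumptions, and
the pipeline propagates units correctly end to end.  What they do not
show: robustness to photophysics (triplet blinking, afterpulsing),
membrane-bound or anomalous diffusion, cell-to-cell optical variability,
or motion of the cell during acquisition — none of which the generator
emulates.

## Known limitations

* Single-component free-diffusion fits only; no two-component, triplet,
  flow or anomalous-diffusion terms.
* Cross-correlation is reported as an amplitude significance readout, not
  converted into bound fractions (that would require overlap-volume
  calibration).
* The bleach model is mono-exponential; bi-exponential decays are
  approximated by their dominant component.
* Brightness is independent of D: the generator does not emulate
  brightness changes upon complex formation.
* Compartments are independent parameter sets; no nuclear-cytoplasmic
  exchange kinetics.
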