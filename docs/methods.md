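# Methods

This package simulates and analyses a single-case visual-extinction
experiment in which the question is not *whether* two visual areas respond,
but whether fluctuations in their *effective connectivity* before a
stimulus arrives determine whether a bilateral stimulus is consciously
seen. Every analysis stage (prestimulus-baseline GLM, FIR peristimulus
estimation, dynamic causal modelling with family-level Bayesian model
comparison) is run against synthetic data whose seen/unseen structure is
*caused* by exactly the mechanism the analysis is designed to detect, so
the pipeline can be validated end to end.

## The paradigm

Nine event-related runs of 35 trials each (23 bilateral, 6 unilateral
left, 6 unilateral right; 207 + 54 + 54 in total), stimulus duration
140 ms in runs 1–6 and 120 ms in runs 7–9, inter-trial intervals drawn
uniformly from 4–20 s, TR = 2 s. Bilateral trials are classified by the
report: *BS* (both sides seen) vs *BU* (left stimulus extinguished,
response "right"). Unilateral trials are *UL*/*UR* when correctly
reported. Bilateral trials answered "left" or "none" do not fit the
seen/unseen dichotomy; they are labelled `other` and excluded from BS/BU
analyses (a conservative choice — the binary framing is the object of
study). Responses are simulated either per-trial (Bernoulli) or with
exact counts, the latter reproducing fixed observed totals such as 94
unseen of 207 bilateral trials (45%).

Run length is not derivable from the trial counts alone; the default is
420 scans (840 s), which accommodates the worst-case ITI draw plus a 9 s
peristimulus tail.

## The generative model

Two regions (index 0 = left, lesioned hemisphere; 1 = right) follow
bilinear neural dynamics

    dz/dt = (A + Σ_j u_j B_j) z + C u

with three inputs: (1) a 7 s prestimulus boxcar before *every* bilateral
trial, (2) a stick at every bilateral onset, (3) the same 7 s boxcar
restricted to BS trials. Inputs 1–2 drive both regions (the laterality of
driving input entry is not identifiable from the analysis design; both-
region entry is the default and is configurable). Input 3 drives nothing
and only modulates: its B matrix is the *only* difference between seen and
unseen trials, so any seen/unseen asymmetry in the data is connectivity-
mediated by construction.

Default coupling (Hz): `A = [[-0.5, -0.1], [-0.1, -0.5]]` (self-inhibition
with weakly inhibitory reciprocal coupling) and seen-prestimulus modulation
`B3 = [[0.30, 0.25], [0.15, 0.10]]`, i.e. self-inhibition released more on
the left (60%) than the right (20%), and both extrinsic connections pushed
from mildly inhibitory to excitatory, the right-to-left change the larger.
These magnitudes are configuration, chosen to reproduce the qualitative
connectivity pattern under study; stability (negative real parts of the
eigenvalues of `A` plus every on/off combination of modulations) is
enforced by a validator. Driving strengths are 0.15 Hz (prestimulus
boxcar) and 1.0 Hz (stimulus stick), giving peak BOLD excursions of a few
percent.

Neuronal states pass through the balloon–Windkessel hemodynamic model
(vasodilatory signal, blood flow, venous volume, deoxyhemoglobin; flow,
volume and dHb integrated in log space for positivity) with the standard
constants κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2 s, α = 0.32, ρ = 0.4,
V₀ = 0.04, and the classic BOLD observation equation (k₁ = 7ρ, k₂ = 2,
k₃ = 2ρ − 0.2), in percent signal change. Integration is fixed-step RK4 at
`fine_dt = TR/16 = 0.125 s` with piecewise-constant inputs; scan-rate
series are decimated at scan onsets. The integrator is one shared
implementation (numba-compiled) used by both the generator and the DCM
inversion, so the generating model is exactly a point in the model space
being searched.

Observation noise is white Gaussian on BOLD (SD 0.3% signal by default) —
a deterministic-DCM world with measurement noise only. A slow sinusoidal
drift (period 300 s, amplitude 0.5%) and per-run constant offsets (SD
0.3%) are added so that the high-pass and run-concatenation handling of
the analysis stages is actually exercised. Runs are simulated
independently and concatenated.

What the generator does *not* emulate: physiological (cardiac/
respiratory) noise, spatially correlated noise, trial-to-trial neural
variability beyond history effects, lesion anatomy, or endogenous
connectivity fluctuations that are not time-locked to the trial — the
modulation switches on exactly 7 s before onset. Passing tests therefore
show that the analyses recover the *modelled* mechanism at realistic SNR,
not that real extinction data would behave this way.

Volume mode embeds the two ROI series as Gaussian blobs (σ = 1 voxel) in
opposite x-halves of a small grid, with white noise in every voxel, and
records ground-truth blob masks for recovery checks.

## GLM

Eight condition regressors — for each of UL, UR, BS, BU a *baseline*
regressor (6 s boxcar starting 7 s before onset, leaving a 1 s gap before
the stimulus) and an *evoked* regressor (stick at onset) — convolved with
the canonical double-gamma HRF (response gamma peaking at 6 s, undershoot
at 16 s, ratio 6:1, 32 s support, unit peak). The baseline and evoked
regressors of a condition are correlated by construction and are *not*
orthogonalised, so baseline effects cannot be re-expressed as evoked
effects. Boxcars are half-open `[start, end)` on the fine grid and sampled
at scan onsets. Nuisance columns: six motion stand-ins (seeded smoothed
random walks), a per-run discrete-cosine basis containing all
non-constant cosines with period above 128 s, and per-run intercepts.

Fitting is OLS via pseudoinverse (white-noise error model — the synthetic
noise is white by construction; no AR prewhitening, a deliberate
divergence from typical fMRI packages). Contrasts use
`t = c'β / sqrt(σ² c'(X'X)⁻c)` with one-sided p-values and two threshold
rules: p < 0.001 uncorrected, or Bonferroni p < 0.05 across in-mask voxels
(the stand-in for random-field FWE control, which is out of scope).
Zero-residual-variance voxels get t = 0 and a flag; residuals at numerical
rounding level (≤ n·10⁻²⁰ summed squares) count as zero variance. Overlap
between suprathreshold masks is reported as `round(100·|a∩b|/|a|)`,
undefined for an empty reference mask.

## FIR peristimulus estimation

Per condition, eight contiguous 2 s bins spanning [−7, +9) s around onset.
The design is the FIR convolution form: a column's value at a scan is the
number of events of that condition placing the scan in that bin, so
overlapping trials are deconvolved by joint least squares together with
the nuisance columns. (A nearest-event assignment variant was evaluated
and rejected: it leaves the preceding trial's response unmodelled whenever
the ITI is shorter than the window, which systematically biased the
prestimulus bins.) Events whose window precedes the first scan of a run
are dropped with a log message. The BS − BU difference curve carries a
per-bin dispersion from the fit covariance,
`sqrt(σ² c'(X'X)⁻c)` — a fit-based SD rather than an across-trial SD,
which the joint-deconvolution design does not define trial-wise.

## DCM and model comparison

The 16-model space is the 4×4 factorial over which connections input 3 may
modulate: intrinsic level ∈ {both, left, right, neither} (diagonal B
entries) × extrinsic level ∈ {both, left→right, right→left, neither}
(off-diagonal entries). All models share the same driving inputs; B is
additive, so modulated coupling is literally `A + B`.

Priors (Gaussian, diagonal): A diagonal ~ N(−0.5, 1/256) Hz, A
off-diagonal ~ N(0, 1/16), free B entries ~ N(0, 1/16), C entries
~ N(0, 1), log-scaling of κ and τ per region ~ N(0, 1/64), observation
log-precision ~ N(0, 1). The B variance follows the canonical shrinkage
scale of deterministic DCM; a much looser prior makes the Occam penalty
for redundant modulation parameters so large that the comparison becomes
overconfident about "no modulation" on null data, which a calibrated
procedure should avoid.

Inversion is variational Laplace: regularised Gauss–Newton ascent on the
free energy with central finite-difference sensitivities, Levenberg-style
damping (doubled whenever a proposal would lower F, halved on acceptance),
and interleaved 1-D Newton updates of the noise log-precision (clipped to
[−8, 12] to keep the precision finite on exactly-fitting data). Proposals
whose A or A + B₃ has a non-negative dominant eigenvalue are rejected
through the damping mechanism rather than clipped. Convergence: |ΔF| <
10⁻² on four consecutive iterations, cap 128 iterations; accepted steps
never decrease F, and the iteration trace is returned. Per-run constants
and the per-run 128 s cosine basis are projected out of both data and
prediction; the projector is identical across models, so free energies
remain comparable, and the effective number of observations is reduced
accordingly.

Model posteriors are the softmax of free energies under a uniform prior
(log-sum-exp stabilised). Family posteriors reweight model priors so every
family carries equal prior mass, then sum members. The two-step search
fits all 16 models once, picks the intrinsic family with the highest
posterior (averaging over extrinsic uncertainty), then compares the four
extrinsic variants within that family. Ties break to the lowest
enumeration index with a warning. The connectivity report gives, per
connection, the baseline strength A, the modulation B, the modulated
strength A + B, the percent change in self-inhibition −100·B_ii/A_ii for
intrinsic connections (undefined at A_ii = 0), and whether an extrinsic
connection switches sign from baseline to modulated.

## Problem sizes and numerical choices

GLM and FIR analyses run at the paradigm's full scale (9 runs × 420 scans
= 3 780 scans). Model-comparison studies (16 inversions per dataset) use a
reduced paradigm — 3 runs of 10 bilateral + 2 + 2 unilateral trials in 150
scans each (450 scans, safe for the worst-case ITI draw) — which the
two-region design makes statistically ample: the strongly modulated
ground truth is recovered with family posterior > 0.99. Named scenario
constructors fix the study conditions: `strong_modulation_truth()` (all
four modulations 0.2–0.35 Hz, noise SD 0.05%) for recovery/replication
studies and `null_truth()` (no modulation, noise SD 0.3%) for calibration.

Finite-difference steps are 10⁻³ prior SDs (floor 10⁻⁴); the RK4 step
TR/16 changes states by < 10⁻⁶ under step halving. Percentages round to
the nearest integer, ties away from zero. All randomness flows from a
single master seed through `numpy.random.SeedSequence` spawns, and a
fixed configuration reproduces every output byte for byte (timings are
written separately from the report).

## Known limitations

- The hemodynamic forward model uses fixed canonical constants with only
  κ and τ free (log-scaled, tightly shrunk); full hemodynamic estimation
  is not attempted.
- The free-energy landscape is explored from the prior mean only; no
  multistart. On the tested regimes this is sufficient (monotone traces,
  recovery across seeds), but pathological datasets could converge to
  local optima flagged only by `converged=False` or poor fits.
- Prestimulus modulation is time-locked to the trial; endogenous
  fluctuations with their own dynamics are not modelled, which makes the
  earliest peristimulus bins conservative relative to a world in which
  elevated coupling precedes the boxcar.
- Volume mode is a minimal spatial wrapper (Gaussian blobs, white noise);
  it supports recovery and overlap checks, not realistic spatial
  inference.
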