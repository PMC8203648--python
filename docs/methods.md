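# Methods

`stimfc` implements a stimulus-driven (opto-)fMRI analysis for block-design
cohort studies in the anesthetized mouse: a stimulation-paradigm model with
hemodynamic design matrices, voxel-wise GLM statistics with subject-level
FDR control, atlas regionalization with event-related BOLD averaging and
group comparison, and a differential functional-connectivity (FC) network
procedure that summarizes group differences as signed edge counts between
composite anatomical nodes. Because no raw scanner data ships with the
package, a synthetic-cohort generator produces ground-truthed BOLD data
with the statistical structure the analysis assumes; every stage is
validated against that ground truth.

## Stimulation paradigms and the hemodynamic model

A paradigm is an ordered list of non-overlapping events, each with a kind
(`heat`, `laser`, or `costim` for simultaneous laser-heat co-stimulation),
an onset, a linear ramp, and a plateau. The default co-stimulation protocol
is a 65-min run of 16 heat-class stimuli (20 s each: 5 s ramp, 15 s
plateau) at a constant 100 s stimulus interval, every 2nd heat stimulus
combined with laser, and one laser-only stimulus interleaved between
consecutive heat-class stimuli — 8 heat-only, 8 co-stimulation, and 16
laser-only events. The wild-type heat protocol is three ascending sets of
40/45/50/55 °C stimuli at a 3 min 40 s interval after a 2-min rest.
The first heat-class onset defaults to 100 s, placing all 32 stimuli
comfortably inside the 65-min acquisition with a pre-stimulation rest used
for percent-signal-change baselines.

The hemodynamic response function (HRF) is a two-gamma form
h(t) = g(t; p₁, d₁) − g(t; p₂, d₂)/ρ, where each lobe g is a gamma density
re-parameterized so its mode sits at the requested peak time
(shape = peak/dispersion + 1, scale = dispersion). Defaults: response peak
p₁ = 5 s, undershoot peak p₂ = 15 s, response/undershoot ratio ρ = 6, unit
dispersions, unit-peak normalization. With these defaults the argmax of the
composite response sits 1 ms before p₁ (the undershoot pulls it one grid
step early at 1 ms resolution). All parameters are configurable.

Design matrices contain one regressor per stimulus kind present — a
trapezoidal stimulus function (ramps are part of the protocol, so a pure
boxcar would misplace response onsets by seconds) convolved with the HRF on
a 0.1 s grid and sampled at the volume times — plus constant and linear
drift columns. Laser pulse structure (10 Hz) is modeled as a constant
block: pulse-level detail is invisible at a 4 s effective repetition time.
Designs are memoized per paradigm, since cohort simulation and per-subject
GLMs reuse the identical matrix.

## Synthetic cohorts

`make_atlas` parcellates an ellipsoidal brain-like mask into compact,
contiguous regions by multi-source breadth-first region growing from
seeded voxels. The default geometry is desk-scale — a 16×16×8 grid with 20
regions and 975 effective volumes — because every property the analysis is
tested on is geometry-independent; the full acquisition geometry (64×64×22,
1950 volumes at TR 2 s, 196 regions) is supported.

Per subject, the region signal in percent units is

    pct_r(t) = Σ_c a_{r,c} · m_{g,c} · γ_r · x_c(t)  +  Σ_k s_k z_k(t) ± …  +  ε_r(t)

where `a` is the per-region per-condition amplitude (% signal change),
`m` the per-group multiplier, `γ_r` a Bernoulli gate implementing the
per-region activation probability (so the ≥50 % region-selection rule can
be exercised), `x_c` the HRF-convolved condition regressor, `z_k` i.i.d.
standard-normal latents shared by planted coupled region pairs (same sign
on the positive-correlation channel, opposite signs on the negative
channel, amplitude `s_k`), and `ε_r` white region-level noise with sd =
`noise_sd`. The raw signal is `baseline · (1 + pct/100)`; each voxel adds
independent white noise of the same sd on top of its region's signal. The
latent draw happens for every coupling regardless of group so that control
and treated subjects with the same seed consume identical random streams —
this makes group-label exchangeability an exact symmetry on null cohorts.

Noise enters at both levels deliberately. Region-level noise keeps region
means from becoming effectively noise-free (a region mean over ~50 voxels
suppresses voxel noise by ~7×), which matters because global-mean removal
redistributes a small fraction of any planted latent into every region;
without region-level noise that leak dominates the residual variance and
every null FC edge becomes significant, contradicting the null-calibration
behavior the analysis is supposed to have.

Subject seeds derive deterministically from the cohort seed via a seed
sequence; identical spec + seed gives bit-identical cohorts.
`simulate_region_timecourses` is a fast path producing the region × time
matrix directly (identical model minus voxel expansion); the statistical
test suites use it so 50–100-seed simulations stay inside a desktop runtime
budget. What the generator does **not** emulate: scanner drift beyond a
linear trend, physiological (cardiac/respiratory) noise, motion, spike
artifacts, susceptibility dropout near the implanted fiber, and spatial
autocorrelation of noise. Passing tests therefore demonstrate correctness
of the analysis under its own statistical assumptions, not robustness to
real-scanner artifacts.

## Preprocessing

Contracts on motion-free data: `discard_initial` (drops saturation volumes
and re-references event onsets), `pairwise_average` (mean of consecutive
volume pairs; TR 2000 ms → TR_eff 4000 ms; a trailing odd volume is
dropped), `spatial_smooth` (per-volume in-plane 2D Gaussian, FWHM in
voxels, reflective boundary), and `temporal_filter`. Motion correction and
affine registration are identity placeholders accepting externally
registered input — synthetic data is generated pre-registered.

The temporal filter is interpreted as: removal of the full linear trend
plus the 9 lowest-frequency Fourier components, followed by 12 s FWHM
temporal Gaussian smoothing. Implementation: project out an orthonormal
basis (constant, centered linear, sine/cosine pairs for cycles 1..n),
apply the Gaussian as a transfer function in the rfft domain, and project
the basis out once more — boundary handling in the smoother would otherwise
re-introduce tiny components of the removed basis, and the final projection
guarantees exact orthogonality (inner products < 1e-6). Filtered signals
are consequently zero-mean, so the pipeline converts to percent signal
change *before* filtering, referencing each voxel to its pre-stimulation
rest volumes. Referencing to the whole-series mean instead would bias GLM
amplitudes by 1/(1 + a·x̄) and is avoided.

## GLM and FDR

Ordinary least squares per voxel (no prewhitening — serial-correlation
handling is unspecified in the source protocol, and the synthetic noise is
white; the decision is isolated so an AR model could be swapped in), t and
two-sided p per stimulus predictor against zero, rank-deficient designs
rejected naming the collinear columns. Multiple-comparison control is
Benjamini–Hochberg step-up at q = 0.05, applied per subject and per
predictor within the brain mask; activation is defined by the p threshold
regardless of sign. The BH implementation delegates to
`statsmodels.stats.multitest.multipletests`; the tests check it against an
exhaustive step-up oracle.

## Regionalization, event-related averages, group comparison

Region time courses are unweighted means over each region's significantly
activated voxels; regions with no active voxel are omitted (and listed),
never zero-filled. A region enters group analyses when its activation
probability — the fraction of subject × condition entries in which it has
at least one active voxel — reaches the selection threshold (default 0.5).

Event-related averages align windows of `pre` (10) timepoints before the
onset volume, the stimulation period (5 timepoints at TR_eff 4 s for a
20 s stimulus), and `post` (15) timepoints after it, averaged over the
condition's presentations (8 for co-stimulation). Each window is referenced
to the mean of its own pre-period: raw-unit inputs are converted to percent
change by dividing by that baseline; percent-unit inputs are baseline-
subtracted (subtraction is what makes the ERA exactly invariant to additive
constants). Truncated windows drop the event with a warning.

The group comparison runs, per region, a one-factor repeated-measures
ANOVA with the window timepoint as the within-subject factor and group as
the between-subject factor (a mixed ANOVA via `pingouin.mixed_anova`),
Tukey HSD post hoc on the group factor, and Bonferroni correction across
regions. The significance call uses the ANOVA group effect; the factor
structure sits behind one interface so a timepoint-wise alternative can be
swapped. Direction is reported from the difference of stimulation-window
means (treated − control: enhanced/reduced) with the SEM of a difference
of means. Zero-variance degenerate inputs yield a NaN p (never a crash)
and an exact zero mean difference.

Amplitude maps take, per voxel or region, the maximum percent-signal-change
magnitude within one condition's event windows (onset to stimulus end plus
a 16 s hemodynamic lag, baseline-referenced per event), so events of other
conditions at a 100 s interval do not contribute.

## Differential FC networks

Per subject and condition: global-mean removal (the cross-region mean at
each timepoint is subtracted — this cancels the stimulus-locked component
shared by responding regions), then full-length Pearson correlations
between all region time courses. Constant regions yield flagged undefined
entries, not zeros. Group pooling is Fisher-z: tanh(mean(atanh r)) with
clipping at |r| = 1−1e-7, averaging undefined entries over the defined
subset.

Dual-channel thresholding keeps the `n_pos` strongest positive (pCorrs)
and `n_neg` most negative (nCorrs) correlations among the selected
regions — with 100 regions and 500 edges per channel the mean node degree
is k = 2·500/100 = 10 per channel. Tie-breaking at the boundary is stable
(|r| descending, then region-index pair ascending), so edge sets are
invariant to any strictly monotone transform of r within each sign class.

Differential edges: for every edge in the universe — the union of both
groups' thresholded channels — a two-tailed Student's t test
(homoscedastic, or paired for matched designs) compares the groups'
subject-level Fisher-z values at P ≤ 0.05, uncorrected. The tests run on
the z scale because that is the scale on which the procedure itself argues
correlations are normally distributed; regions missing in a subject are
excluded pairwise. Significant edges get a sign: +1 treated > control,
−1 control > treated. Composite aggregation sums these signed indicators
over the constituent region pairs of each composite-node pair and both
channels — seven control-greater plus one treated-greater constituents give
a net FC of −6 — and suppresses edges with |net| ≤ the display threshold
(4 and 6 are the reference displays) from the rendered network while
retaining the full matrix. Edges can be pseudo-directed from a directed
structural-connectivity prior (projections "synapse" on the target): u→v
when only that projection is known, bidirectional when both are, undirected
and flagged when the prior is silent. `compare_conditions` reports edge-set
overlap between displayed networks and, per shared edge, which network's
mean |z| is stronger.

One property of the published procedure deserves note: thresholding
selects edges by the *same* group means the t test then compares, so
edges selected from noise extremes reject far above the nominal alpha
(circular selection). The null-calibration suite therefore measures the
per-edge error rate over the full edge universe, where the 5 % nominal
rate is exact; and the end-to-end recovery suite is designed so the
thresholded universe contains genuine edges rather than noise extremes —
100 regions (which also keeps the global-mean leak of a planted latent
negligible: leak variance (2·0.8/100)² ≪ region noise 0.04), one shared
background coupling present in both groups, a stronger group-specific
planted coupling, and a 1-edge positive channel. Under that design the
expected per-seed recovery probability is ≈ 0.95 (one honest null edge at
alpha 0.05), against the ≥ 90 %-of-seeds requirement.

## Pipeline and reproducibility

`run_pipeline` sequences simulate → preprocess → GLM → regionalize → ERA →
FC → differential networks; all randomness flows from the single config
seed (verified by double-run checksums), every stage failure names the
stage and offending subject, and all intermediates can be written in
standard formats (NIfTI volumes, TSV tables, GraphML networks, YAML/JSON
provenance). The `stimfc` CLI exposes each stage as a subcommand over a
run directory so stages are independently inspectable. Config defaults
equal the protocol values throughout (65-min paradigm, q = 0.05,
selection 0.5, 500 edges/channel, alpha 0.05, group sizes 5 control vs 9
activated).

Problem sizes in the shipped tests are desk-scale by design: 5–20 regions
and 250–975 volumes for unit tests, 100 regions for the FC-recovery suite,
50–100 seeds for the stochastic suites, with the region-level fast path
replacing voxel simulation wherever only region time courses enter the
quantity under test.

## Known limitations

- No prewhitening: GLM p-values are exact only for white noise.
- The mixed-ANOVA group test assumes sphericity across timepoints for the
  within factor; only the between-group effect feeds the significance call.
- Pairwise exclusion of missing regions makes per-edge sample sizes vary;
  no minimum-n guard beyond two subjects per group.
- The circularity of threshold-then-test (above) is reproduced faithfully,
  not corrected.
- Identity placeholders for motion correction and registration mean real
  scanner data must arrive pre-registered.
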