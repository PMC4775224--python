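# Methods

## Scope and model

The package analyses (and simulates) single-molecule dumbbell experiments
in which an RNA aptamer, held between two optically trapped beads through
DNA handles, is repeatedly refolded under low load and unfolded by a linear
trap-separation ramp while donor/acceptor photon counts report the FRET
efficiency between its P3 and L5 helix arms.  Two coupled state spaces are
modeled:

- a **tertiary chain** UF ⇄ A ⇄ B ⇄ C (unfolded, arms apart, weakly
  bound, docked), a continuous-time Markov chain active during the
  refolding period, read out through FRET;
- a **secondary-structure conformation** F / F′ / F″ set by the tertiary
  state reached at ramp start (A→F, B→F′, C→F″), read out through the
  force-extension curve (FEC): F opens in three rips, F′ in one
  mid-force rip plus a tiny (3 nm) P3 rip, F″ in a single high-force rip.

## Mechanics

Polymer elasticity uses the Marko–Siggia interpolation
`F = (kBT/P)[¼(1−x/L)⁻² − ¼ + x/L]` with no enthalpic stretch term — two
parameters per polymer, adequate below ~35 pN.  The inverse is a bracketed
Brent root find on x/L ∈ [0, 1) (relative tolerance 1e-10 in the force
balance, 1e-12 standalone); chains in series add extensions at equal
tension.  The dumbbell force balance `F/k_trap + x_mol(F) = separation` is
solved per frame by bracketed root finding, warm-started from the previous
frame's force.  Mechanics are quasi-static: bead relaxation (~ms) is fast
compared with the 50-ms frames, so Brownian dynamics are not simulated and
per-frame measurement noise is modeled directly (extension 0.5 nm, force
0.1 pN RMS, typical of dual-trap data averaged over 50 ms).

Default mechanical parameters: handles of 340 + 680 nm contour (1 kb +
2 kb dsDNA) at 40 nm persistence length; unfolded RNA at 1 nm persistence
length with 78 nm total releasable contour, split (30, 26, 22) nm over the
three F-class rips, (75, 3) nm for F′ and 78 nm for F″.  The contour gains
were calibrated so that rips are plainly visible discontinuities in the
FEC at the instrument settings used (200 nm/s ramp, 0.3 pN/nm trap,
50-ms frames) while the 3-nm P3 rip stays barely detectable — the
signal-to-noise regime this class of experiment operates in.

Rupture is modeled as a Gaussian-distributed critical force per rip (per
conformation class), not a force-dependent Bell rate: the data being
reproduced constrain rupture-force distributions, not rupture kinetics.
Successive critical forces in one ramp are kept at least 2.5 pN apart so
that consecutive rips always occupy distinct frames at the ~1.8 pN/frame
loading rate.

## Photon model and corrections

Each frame draws a true efficiency `E_t` from the current state's Gaussian
emission (mean, SD), then Poisson counts

    donor    ~ Pois(R·Δt·(1−E_t) + bg_D)
    acceptor ~ Pois(R·Δt·E_t·γ + β·R·Δt·(1−E_t) + bg_A)

with R = 16 000 photons/s, β = 0.13, γ = 1, backgrounds 10 counts/frame by
default.  The correction `I_D = γ(d−bg_D)`, `I_A = (a−bg_A) − β(d−bg_D)`,
`E = I_A/(I_A+I_D)` is the exact inverse of this model in expectation
(applying γ to the donor channel is algebraically the usual
`E = I_A/(I_A+γI_D)`), so corrected efficiencies recover the configured
levels with bias < 0.005; E is never clamped to [0, 1].  β is estimated as
the acceptor/donor ratio of background-subtracted means over frames known
to have E = 0; γ from |ΔI_A|/|ΔI_D| across a FRET transition.  Bleaching
(exponential per dye) and acceptor blinking (telegraph) are implemented
but default to off: the Trolox/oxygen-scavenger protocol suppresses both,
and analysed records are the pre-bleach portions.

Per-state emission defaults are the study conditions the analysis is
validated against: APO 0.46, WB 0.73 (variance 0.010), thiamine-bound
0.64 (0.005), TMP-bound 0.69 (0.003).  Quantities without an established
reference value were fixed once at plausible levels: SB mean 0.80 (the high-force cluster
FRET centroid), SB variance 0.002 ("low-variance" docked state), APO
variance 0.004.  The relaxed unfolded coil during refolding emits at 0.44
(SD 0.08) — deliberately 0.02 below APO, since the unfolded and
arms-apart states are spectroscopically nearly identical and are
distinguished only dynamically; the stretched post-rupture state on the
ramp emits at 0.03.  Within-state emission noise is uncorrelated between
frames; real dye photophysics (spectral fluctuations, slow drift) would
add temporal correlation that this generator does not emulate, so
passing recovery tests demonstrate correctness of the estimators under
shot-noise-dominated conditions, not robustness to correlated drift.

Condition kinetics (1/s): UF→A 2.0, A→UF 0.3, A→B 1.0, B→A 0.1, plus
B→C 0.5, C→B 0.05 under TPP (docking available) and B→C = 0 for thiamine
and TMP (analogs lacking the phosphates needed to dock).  The kinetic constants were chosen once to match the qualitative
behaviour of the assay (fast initial fold, near-irreversible docking on a
~1 s timescale); all rate-recovery tests compare against the configured
generator rates.

## Rip detection

The basic rule — rips as frames where the median-filtered extension jumps
by more than `min_jump` (default 5 nm) between consecutive frames — is
kept, with two refinements the ramp geometry makes necessary.  First,
the ramp itself advances the extension 4–9 nm per frame at these
compliances, so steps are compared against a running-median **baseline** of
neighbouring steps rather than against zero.  Second, rupture at fixed
trap separation also relaxes the tension by ~2–3 pN (against a ~0.1 pN
noise floor), so a step exceeding 0.3·`min_jump` whose force falls more
than 0.6 pN below the local loading trend is also accepted; frames within
two of an accepted rip are excluded from this weaker rule because the
branch change biases both baselines (a genuine next rip needs ≥ 3 frames
of reloading).  The pure-extension rule alone misses ~20 % of low-force
rips at the default settings; the two-channel rule recovers ≥ 95 % of
F-class rip triplets with opening forces within 0.5 pN of truth, while the
3-nm P3 rip (force drop ~0.35 pN) stays below both gates.

F₁/₂ is the force at the last pre-rip frame.  Δx is the difference of
double-WLC branches at F₁/₂, with the released contour of each inter-rip
segment fitted directly as `mean[(x − x_handles(F))/z_rna(F)]` over frames
above 1 pN; a post-rip branch whose mean residual exceeds 5 nm warns but
does not fail.  The opening FRET is the corrected E at the last pre-rip
frame.

## State thresholds and segmentation

Opening events are z-scored per axis (pN and FRET differ by two orders of
magnitude) before k-means; centroids are reported in original units and
sorted by force, and thresholds are midpoints of adjacent sorted centroid
coordinates, the simplest convention that reproduces the reference
threshold values (0.57 / 0.74 and 11.5 / 21.0 pN); it requires k = 3.

Trajectory segmentation assigns APO/WB/SB **per segment, not per frame**.
The numbers themselves force this choice: the WB mean (0.73) lies 0.1
frame-SD below the upper threshold (0.74), so with any stationary frame
noise at the WB variance, roughly half of all WB frames lie above
the threshold and a frame-wise rule necessarily splits the state's
distribution and biases its statistics.  Classifying quasi-stable
stretches of the trajectory by their mean level — the level an analyst
assigns a segment by eye — leaves the within-state distribution intact.
The implementation:

1. recursive binary change-point detection on E, splitting only where the
   standardized mean shift exceeds `split_z` (default 4.0, above the null
   maximum for ~10²–10³-frame records), with the frame noise σ estimated
   robustly from median absolute successive differences and no segment
   shorter than `excursion_tolerance + 1` frames;
2. a level-aware smoothing decode: Gaussian levels for the classes
   present are re-estimated from the provisional labels and the most
   likely label path under a symmetric per-frame switching prior
   (`p_switch` = 0.02) is decoded, which places dwell boundaries
   near-optimally and absorbs undetectably short dwells whole;
3. each decoded segment is classified by its mean E against the
   thresholds (below t_low APO, above t_high SB, between WB).

Brief excursions — one or two frames beyond a threshold — therefore never
change the assigned state; for an effectively noise-free series the
frame-wise band labels with short-excursion persistence are used directly.
The operation is deterministic and idempotent.  Non-finite E values are
INVALID and act as hard boundaries.  On default-condition synthetic data
this recovers pooled WB statistics within 0.01 of the configured mean and
within 10 % of the configured variance (the information-theoretic ceiling,
evaluated with oracle boundaries, is ~0.006 below the configured mean),
and frame-level accuracy against truth is ~94 %.  Residual confusion is
concentrated where it must be: unfolded-coil vs APO frames (emissions 0.02
apart) and WB dwells shorter than ~1 s against the SB level 0.7 frame-SD
away.

The pipeline segments refolding frames plus pre-first-rip ramp frames
below 10 pN; everything after the first detected rip — and whole ramps
with no detected rip, which are records of molecules that failed to
refold — is masked UNFOLDED.

The global FRET histogram (bin 0.025) is fitted to a sum of four Gaussians
by bounded nonlinear least squares on binned counts, adding components
greedily at the largest positive residual so that data with fewer
populations leave surplus components at near-zero amplitude; an unbinned
Gaussian-mixture fit serves as an independent cross-check in the tests
only.  Three components map onto APO/WB/SB; the fourth captures the
unfolded/baseline population and is reported but not mapped to a state.

## HMM kinetics

Refolding E series are concatenated with per-trace segment lengths so no
transition is counted across a boundary.  The HMM has Gaussian emissions
on E and a tridiagonal transition matrix whose off-band zeros are exact at
initialization and preserved by the Baum–Welch multiplicative update
(fitting and decoding use hmmlearn).  UF and A are initialized at the
low-FRET level ∓0.02 to break their emission symmetry; B and C at the
data's 60 % and 90 % quantiles.  Multistart (3 restarts, jittered means)
keeps the best final log-likelihood; non-convergence is reported on the
model, never raised.

Directional rates use the maximum-likelihood dwell estimator
`k(X→Y) = N(X→Y) / T_complete(X)`: decoded transitions to Y divided by the
total time in complete dwells of X, whose reciprocal is reported as the
directional transition time.  (The naive "reciprocal of the mean dwell
preceding an exit to Y" estimates the *total* exit rate of X, not the
directional rate, whenever a state has two exit channels — the two
coincide only for single-exit states.)  Dwells truncated by a segment
boundary are censored and excluded from both numerator and denominator,
avoiding the downward bias of cut-off dwells.  Pairs with zero observed
transitions are reported absent with an explanatory note; rates at or
above half the frame rate are flagged as lower bounds, since faster
kinetics cannot be resolved at 20 frames/s.  Transition-matrix-derived
rates (p/Δt) are available as diagnostics.

Rate recovery was validated at 20 frames/s with emission separations
≥ 3 SD and rates spanning 0.4–2 /s: all six directional rates recover
within 20 % (typically within 12 %) from 50 traces × 30 s; the residual
negative bias comes from dwells shorter than one frame, which the decoder
cannot see.

## Problem sizes and numerical choices

Recovery checks use 50 traces × 30 s refolds per condition (~30 000
frames), 20 independent 150-event scatters for threshold derivation, 10⁴
donor-only frames for β, 200 traces per class for rip-count fidelity, 10³
random parameter draws against the WLC grid-inversion oracle and 10²
10-frame series against exhaustive 4¹⁰-path enumeration for the Viterbi
decoder — sizes at which every statistical tolerance has ≥ 3σ margin while
the whole suite runs in about a minute.  All randomness flows from a
single seed per run through `numpy.random.SeedSequence`; identical seeds
give bitwise-identical traces.  Ties and degenerate inputs: zero-variance
event scatter and k < 2 are rejected in clustering; empty FRET series and
inverted thresholds are rejected in segmentation; a zero-photon frame
yields NaN efficiency and an INVALID label.

## Known limitations

- Quasi-static mechanics: no bead hydrodynamics, no force-overshoot
  dynamics at rupture; rupture forces are distributions, not Bell-model
  kinetics, so loading-rate dependence is out of scope.
- Emission noise is white; correlated photophysical drift and true
  photon-by-photon likelihoods are not modeled.
- The unfolded coil and APO state are intentionally near-degenerate in E;
  frame-level accuracy between them is limited to what dynamics reveal.
- Equilibrium constant-force hopping analysis and R₀ computation from
  spectra are out of scope; hairpin control constructs are representable
  only as generic two-state configurations.
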