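# Methods

## Stereo geometry and the perceived-distance teaching signal

For a midline object, geometric egocentric distance follows from
interocular distance `I`, vergence `v` and horizontal disparity `δ`
(crossed disparities negative):

    D_geom = I / (2 · tan((v − δ) / 2))

Interfaces take degrees; conversion to radians is internal.  Object angles
`v − δ` below 1e−6° are rejected rather than mapped to astronomically large
distances, and angles ≥ 180° are geometrically meaningless and rejected
too.  The default `I = 0.065 m` is the typical adult interocular distance;
descriptions of this quantity as "6 mm to 7 mm" in the modelling literature
are a unit slip (6–7 cm is the anatomical range), so the package uses
metres and makes `I` configurable.

Humans do not report `D_geom` veridically: near distances are
overestimated and far ones underestimated.  The perceived-distance signal
is therefore `D_geom` evaluated with a corrected disparity `δ′ = f(δ)`.
The exact psychophysical correction is not uniquely established, so the
correction is a pluggable callable; the default

    f(δ) = k1 · k2 · tanh(δ / k2),   k1 = 1, k2 = 2°

is odd (fixation is a fixed point), compressive (|f(δ)| ≤ |δ|), and
produces exactly the over/under-estimation pattern: shrinking a crossed
disparity pushes the estimate out, shrinking an uncrossed disparity pulls
it in.  `k2` sets the disparity scale at which compression saturates.  Any
other correction (including the identity, which recovers `D_geom` exactly)
can be passed in its place.

## Disparity, vergence and size tuning

**Disparity cells.**  Five classes with Gaussian profiles on a
[−4°, 4°] working range.  Tuned-excitatory (TE) cells are single Gaussians
(peaks within ±1.5°).  Tuned-near/near cells (peaks in [−4°, −1.5°]) and
tuned-far/far cells (peaks in [1.5°, 4°]) are differences of Gaussians with
a suppressive lobe of the same width displaced by half a width toward the
anti-preferred side (`δ_i + σ_i/2` for near-type, `δ_i − σ_i/2` for
far-type), plus a small baseline.  The lobe displacement realises the
push–pull asymmetry of the two families; the half-width offset is a
package choice where the literature formula is ambiguous.  Tuned-inhibitory
cells are omitted — they are TE cells with negative readout weights, which
the linear readout can produce on its own.

Widths follow the rule σ_i = |δ_i|, pinned to 10 arcmin for peaks within
10 arcmin of zero.  The default population has 40 cells, 8 per class,
preferred disparities evenly spaced within each class range.  The class
allocation is not dictated by physiology; an even split keeps the basis
balanced.  Base amplitudes (A1, A2, A3) = (1, 0.5, 0.1) per
difference-of-Gaussians cell are rescaled jointly so every cell's maximum
response is 1 on a 0.01° grid — "approximately equal maxima" realised as
exact grid-peak normalization.  Negative values from the subtracted lobe
are clipped at zero by default (responses stand for firing rates); the
unclipped profile is available via a flag.

**Vergence cells.**  Logistic curves `z(v) = 1/(1 + exp(−(v − v_i)/T_i))`,
five cells with thresholds evenly spaced over the working vergence range
[1°, 15°] and a common slope.  The default slope is 0.75°.  This value
matters more than it may appear: at zero disparity all disparity responses
are constants, so the distance readout along the δ = 0 slice is spanned by
the five sigmoids alone.  With slopes much shallower than ~1° the slice
cannot resolve the steep near-field portion of the 1/(v−δ) distance law and
the fitted readout becomes non-monotonic in distance; 0.75° gives the basis
enough resolution while keeping the curves smooth over the working range.

**Size cells.**  Gaussians over angular size β ∈ [0°, 3.2°],
`s_i(β) = K · exp(−(β − β_i)²/σ_i²)`.  The gain `K` multiplies the whole
curve, so preferred size and width are distance-invariant by construction.

## Distance network and delta-rule training

The MT basis is the full Cartesian product of the two populations
(40 × 5 = 200 units), `B_i(δ, v) = a_i(δ) z_i(v)`, and the LIP readout is
linear, `D = Σ w_i B_i`.  Weights are trained with the classical online
delta rule: samples shuffled every epoch with a seeded generator,
`w ← w + η (D_teacher − w·B) B` per sample.  The model is linear in `w`, so
batch least squares over the same design matrix is an exact oracle: its
RMSE lower-bounds the delta rule, which approaches it within a few percent
at convergence.  Divergence (RMSE growing tenfold within ten epochs, or
non-finite) raises with advice to lower the learning rate.  The per-sample
stability bound is η < 2/max‖B‖² ≈ 0.038 for the default populations;
default η = 0.03, 400 epochs.

The default training grid is 30 × 30 over v ∈ [1°, 15°], δ ∈ [−4°, 4°],
intersected with the valid-geometry domain (857 points).  The teaching
signal is capped at a configurable maximum distance so the near-singular
corner (v − δ → 0, distance → ∞) does not dominate the squared-error loss.
Two caps are used deliberately:

* the network module's default cap is 20 m, for fitting the distance map
  over the full working range;
* the experiments module trains the feedback readout with a 2 m cap,
  roughly twice the farthest default stimulus distance.  With a 20 m cap
  the capped spike still absorbs most of the fitting capacity and leaves
  ±0.5 m errors in the 0.2–1.2 m range where the stimuli live — enough to
  destroy the monotone distance feedback the size module needs.  Training
  the readout over the behaviourally relevant range is the package's
  standing choice for closed-loop runs.

**Error reporting.**  Fit quality is reported as range-normalized RMSE
(NRMSE = RMSE / (max − min) of the teacher).  The teacher spans roughly
two orders of magnitude in metres, so normalizing by its mean or RMS would
be dominated by the capped far corner; range normalization is the standard
NRMSE convention for wide-range targets.  At the defaults the delta rule
reaches ≈4.3% NRMSE, within ~1% of the least-squares floor; with a
realizable teacher (targets generated by known weights over the same basis)
4000 epochs at η = 0.035 recover the readout to NRMSE below 1e−3.

No regularization is applied by default (an optional ridge term exists for
ill-conditioned bases).  The 200-function basis is strongly collinear, so
individual weights are only identifiable on well-conditioned (small)
bases; readout accuracy, not weight recovery, is the meaningful criterion
at full size.

## Size module

**Distance scaling.**  `K = C` (independent), `K = C·d` (farness),
`K = C/d` (nearness).  The defining property of a nearness cell is a
response that *decreases* with viewing distance, which `C/d` implements; a
literal variant `K = d` (increasing) is available behind a flag for
comparison with formulations that state the gain that way, but it
contradicts the behaviour it is meant to model and is off by default.

**Topographic map.**  61 cells tile β ∈ [0°, 3.2°] (tuning width 0.4°),
ordered by preferred size — the package's 1-D proxy for cortical
eccentricity.  Excitatory and inhibitory connections are Gaussians of the
preferred-size difference (widths 0.2° and 0.6°; the surround must be
broader than the centre), with self-connections zeroed.  Because the
inhibitory floor defaults to B3 = 0, inhibition acts divisively and no
explicit excitation/inhibition balance is needed.

**Shunting dynamics.**  The standard membrane form is used: excitation
enters as `+(B2 − S_i)·ΣI_k s_ki`.  A printed variant with a minus sign on
that term would make excitatory input suppressive and violate every
described behaviour of the network; it is kept behind `literal_sign` for
comparison only.  Defaults B1 = 1/s, B2 = 1, B3 = 0 keep activities in
[0, 1].  During a stimulus the decay rate is scaled by the distance
estimate (`B1_eff = B1 · C · d̂`, farness-like decay modulation);
off-stimulus decay is the baseline B1.  Integration is fixed-step RK4
(dt = 5 ms) with Euler available; the Euler path enforces the
`dt·(B1 + E + H) < 1` stability bound, and both paths raise if activity
leaves `[−B3 − 1e−6, B2 + 1e−6]`.  Inputs are held constant across a step,
so event boundaries should align with the step grid (the defaults do).
The closed-form equilibrium `S* = (B2·E − B3·H)/(B1 + E + H)` under
constant input is exposed for verification and matches the integrator to
1e−6.

**Stimulus drive and perceived size.**  The drive to cell k during an
event is `amplitude · K_k(d̂) · exp(−(β_c − β_k)²/σ_k²)`.  By default the
drive centre `β_c` follows the size–distance invariance scaling,
`β_c = angular_size · d̂/d̂_ref`, with the reference distance taken from the
first presentation: a stimulus of fixed retinal size seen farther away
maximally drives cells tuned to proportionally larger sizes.  This is what
produces the topographic shift of activation with distance; with the
scaling disabled (`size_distance_scaling=False`) the drive stays centred on
the retinal size and only amplitudes change, in which case the eccentric
bands receive only the far Gaussian tail and the spread is numerically
negligible.  The second presentation models an afterimage-like weaker
drive (amplitude factor 0.5 by default).

## Experiments

* **Fixed-retinal-size tuning curves**: one angular size (default 2°) at
  three ascending distances (defaults 0.3/0.6/1.2 m — chosen as a
  representative octave-spaced near-range triplet; the empirical paradigms
  do not fix specific values).  Produces per-kind curve families whose
  amplitude ratios equal the gain ratios exactly and whose peaks coincide.

* **Two-presentation paradigm**: first epoch 0.2–1.2 s at the nearest
  distance in every condition, second epoch 2.2–3.2 s at the condition's
  distance, stimulus 0.6° (so the first presentation lands in the least
  eccentric of five ROI bands).  ROI time courses are contiguous-band means
  along the map.  The headline property — the most eccentric band's
  second-epoch mean strictly increases with viewing distance while the
  first epoch is identical across conditions — holds across a ±50% sweep
  of both kernel widths, with either the veridical distance or the trained
  readout in the loop.

* **Synthetic reference**: ROI output plus seeded Gaussian noise
  (sd 0.05 by default), standing in for an empirical curve so the fit
  metrics (CCA, dRMS, Pearson r with percentile-bootstrap CIs over time
  points) run end-to-end.  It is synthetic: passing fits against it
  validate the metric plumbing, not agreement with any measured signal.

Every run embeds provenance (SHA-256 of the resolved configuration, seed,
package version) in its outputs; identical spec + seed gives bit-identical
CSV.

## What the synthetic setup does and does not show

The generator emulates the *structure* of the empirical paradigms: timing,
geometry, population layout, distance conditions.  It does not emulate
measurement physics — no hemodynamic convolution, no scanner noise
correlations, no receptive-field scatter — so passing tests demonstrate
that the circuit mechanisms produce the qualitative phenomena
(distance-scaled amplitudes, bounded shunting dynamics, eccentric spread),
not that the model quantitatively fits any particular recording.  Empirical
fit values can be computed with the metrics module once a real reference
curve is supplied.

## Numerical choices and limitations

* Peak normalization and peak-position checks are grid-based (0.01°
  disparity, 0.02° size); statements about equality hold to grid
  resolution.
* The delta rule at a constant learning rate fluctuates around its floor
  (SGD noise ~5% of the error scale per epoch); convergence claims are
  about the trend and the floor, not per-epoch monotonicity.
* Distance estimates from the trained readout carry basis-limited error;
  with only five vergence channels the readout is accurate to roughly
  ±0.1 m in the near range, which is sufficient for monotone feedback over
  octave-spaced distances but not for finer distance discrimination.
* The map is 1-D; no 2-D cortical sheet, no vertical disparity, optic
  flow or accommodation cues, and no claim about where integration occurs
  anatomically.
* Problem sizes of the shipped experiments (857-point training grid,
  400–4000 training epochs, 61-cell map, 4.2 s simulated at 5 ms steps)
  were chosen so a full run completes in seconds on one CPU while leaving
  all reported properties well clear of their resolution limits.
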