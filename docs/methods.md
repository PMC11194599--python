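# Methods

## Coordinate and angle conventions

All modules share one frame: top view, origin at the bottom-left corner of
the arena bounding box, x rightward, y upward, distances in cm, times in
s, angles in degrees counter-clockwise from +x. Egocentric bearings are
measured CCW from the reference direction (head direction by default), so
+90° means a boundary on the animal's left and 270° on its right. With
this convention, clockwise travel around the inside of an enclosure keeps
the walls on the animal's left — the fact the CW/CCW classifier rests on.

Arena boundaries are directed 2-D line segments: four labeled walls
(N/E/S/W) for squares and elevated platforms, a 1°-resolution 360-gon for
circles (raycast error < 0.02 cm at r = 50 cm), two opposing segments per
thin wall insert, and a closed 4-segment perimeter per rectangular
object. Elevated platforms are geometrically identical to squares; the
distinction is semantic (drop edge vs wall) and does not change any
computation.

## Preprocessing

Tracking files (`t,x,y,hd` at a fixed frame rate, nominally 50 Hz) are
validated against a regular time grid. Missing frames and frames outside
the arena are linearly interpolated (circularly for head direction) when
the gap is ≤ 0.5 s; longer gaps are flagged invalid and excluded from all
maps. Sessions with > 10% of samples outside the arena are rejected.
Running speed is the central-difference displacement rate, boxcar-smoothed
over 0.2 s. All rate estimates use only samples with speed ≥ 2.5 cm/s
(complex stationary behaviors such as grooming contaminate spatial tuning
estimates). Spikes inherit the attributes of their nearest-in-time
tracking sample and are dropped with it.

## Rate maps and stability

Occupancy and spike counts are binned at 2.5 cm (the same grain as the
EBR distance bin), smoothed with a Gaussian of σ = 2 bins (reflective
boundary, which conserves total counts and dwell), and divided. Bins with
less than 20 ms of raw dwell are invalid (NaN). Smoothing numerator and
denominator separately, rather than smoothing the ratio, avoids bias
where dwell is low. Spatial correlations are Pearson coefficients over
bins valid in both maps, NaN below 20 shared bins. Split-half stability
correlates the rate maps of the two temporal halves of a session.

Head-direction tuning uses 6° bins; angular spike counts and dwell are
smoothed with a wrapped Gaussian of σ = 1 bin before division.
Unsmoothed band-restricted curves occasionally put the argmax in a bin
with a few tens of milliseconds of dwell; one bin of circular smoothing
removes these spurious peaks while attenuating the first harmonic of the
curve (and hence the MVL) by less than 1%. The mean vector length is
rate-weighted: `MVL = |Σ r_k e^{iθ_k}| / Σ r_k` over occupied bins.

## Border score

Firing fields are 4-connected components of valid bins with rate ≥ 0.3 ×
peak and area ≥ 200 cm² (32 bins). Wall coverage `cM` is the largest
fraction of one wall's wall-adjacent bin line occupied by a single field,
with never-visited line bins excluded from the denominator (a finite
session that misses two corner bins should not cap coverage below 1).
Circular arenas use the ring of valid bins within one bin width of the
boundary as a single "wall", which qualitatively reproduces the higher
scores such arenas yield. The mean firing distance `dm` is the
rate-weighted mean distance of field bins to the nearest outer boundary,
normalized by half the shorter arena side, hence in (0, 0.975] on a 40 ×
40 grid (bin centers cannot reach the exact arena center or wall). The
border score is `b = (cM − dm)/(cM + dm) ∈ [−1, 1]`; with no qualifying
field the score is NaN and the unit cannot pass the gate.

## Shuffle null and gate

The null model shifts each unit's entire spike train by one uniform draw
from [20 s, T − 20 s], wrapped modulo the session duration — preserving
inter-spike structure while breaking its alignment to behavior — and
recomputes border score and stability; 100 shuffles per unit are pooled
across the population, and the unit-level gate requires both observed
statistics to strictly exceed the pooled 99th percentiles. Both
statistics are computed from the same shuffle draw so the joint gate sees
matched nulls, which makes it conservative (false-positive rate between
0.01² and 0.01; the calibration experiment on 200 untuned Poisson cells
measures ~0–1%). On synthetic flat-rate cells the shuffled border-score
p99 lands near 0.5–0.55, comparable to the published classification
thresholds in this literature (~0.57–0.58), because a near-uniform map
forms one large field with moderate coverage and moderate distance.

## CW/CCW subtype classification

Within 15-cm boundary bands (the same width as the published insert-band
definition), each sample is labeled CW when the egocentric bearing of the
nearest boundary point lies in (0°, 180°) — boundary on the left. The
firing-rate ratio `fr_cw/ccw = (CW spikes / CW time) ÷ (CCW spikes / CCW
time)` classifies gated border cells: > 2 left-egocentric, < 0.5
right-egocentric, otherwise (inclusive) allocentric; an infinite ratio
(spikes only during CW travel) classifies left. Head direction, not
movement direction, defines the bearing by default; a movement-direction
variant is available.

For interior objects the bearing label cannot reproduce the published
sign flip: a bearing label is egocentric and therefore invariant to
whether the boundary encloses the animal or the animal circles the
boundary. What flips is the *rotational* sense — keeping a wall on the
left means circling the arena CW, but keeping an object on the left means
circling the object CCW. The package therefore also provides
`label_by="rotation"` (sign of the heading's tangential component about
the feature's reference point: arena center for walls, object centroid
for objects). Along outer walls the two labelings agree; around objects
the rotational label inverts the ratio for egocentric cells, which is the
package's reading of the object-session phenomenon.

## Egocentric boundary ratemaps

For every retained frame, rays are cast at 120 egocentric angles (3°
bins, evaluated at bin centers) from the animal's position at
`reference + θ`; the first intersection with any boundary segment within
50 cm (half the standard arena; configurable) adds the frame's dt to that
(angle, distance) cell, distances binned at 2.5 cm with an extra final
bin so a hit at exactly the maximum distance is retained. Spikes
accumulate identically. Rates are smoothed spikes over smoothed occupancy
(σ = 1 bin, angular axis wrapped). The EBR mean vector collapses rate
over distance per angle and takes the circular mean; the MVL is computed
over the full distance range (a restricted annulus is configurable).
Frames within one bin of a boundary keep distance bin 0; nothing is
excluded. Mass conservation holds exactly when every ray hits within the
maximum distance (asserted in tests with the cutoff beyond the arena
diameter).

## Theta rhythmicity

Autocorrelograms histogram all pairwise lags within ±500 ms in 10 ms
bins, self-pairs excluded, built symmetric by construction. For the TRI
the center bin is replaced by the mean of the others, the ACG is
mean-subtracted, Hann-tapered and zero-padded to 0.25 Hz resolution; the
TRI is the mean power within ±1 Hz of the largest 4–12 Hz peak divided by
the mean power over 0–50 Hz, and TRI > 5 flags a theta cell. Two caveats
are inherent to this estimator and documented deliberately: (i) for a
*strictly periodic* train the ACG is an impulse comb whose power spreads
evenly over all harmonics, so the spectral TRI of a metronome is modest
even though its rhythmicity is perfect — the time-domain alternative
(`method="contrast"`, theta-band peak/trough contrast of the smoothed
ACG) ranks it at the ceiling and is provided for that reason; (ii) for an
unmodulated Poisson train the TRI is a noise-extreme statistic with
median ≈ 2 and a few percent of draws above 5 at 5 Hz × 600 s, so the
theta-cell false-positive rate at the default threshold is a few percent
— of the same order as the small theta fractions this cell class
exhibits.

## Waveform classes and lateralization

Fast-spiking units are mean rate > 5 Hz with peak-to-trough width
< 300 µs; regular-spiking are ≤ 5 Hz and ≥ 300 µs; everything else (or a
missing waveform) is unclassified. The width is measured on the
largest-amplitude channel as the peak-to-trough sample distance. The
lateralization table counts left/right-egocentric cells by hemisphere and
reports Pearson's chi-square without continuity correction (small-count
tables would otherwise be over-corrected).

## Synthetic sessions

The generator emulates the study conditions the analysis assumes:
20–40 min of foraging in a 1 × 1 m walled arena tracked at 50 Hz.
Trajectories are correlated random walks: speed is a clipped
Ornstein–Uhlenbeck process (mean 15 cm/s, SD 7 cm/s, relaxation 1 s —
mid-range for foraging rats), heading diffuses at 120°/√s with a mild
steering bias away from boundaries inside 4 cm, and steps that would
cross a boundary reflect specularly, which keeps the stationary
distribution near-uniform and lets the animal sample wall-adjacent bins
the way thigmotactic rats do. Head direction is the movement direction
plus wrapped-normal noise (SD 10°), the minimal structure that makes
head- vs movement-referenced comparisons meaningful; real rats decouple
the two far more richly.

Firing models: uniform Poisson; allocentric border,
`λ = base + gain·exp(−d²/2σ_d²)` with `d` the distance to the nearest
boundary (σ_d = 8 cm, a typical boundary-response space constant);
egocentric variants multiply the whole border form by a von Mises gate on
the egocentric bearing of the nearest boundary point (κ = 4, ~68° FWHM,
within the range reported for egocentric boundary tuning; preferred
bearing 90° left / 270° right); Gaussian place fields; and an optional
theta wrapper `×(1 + depth·cos(2πft))`. Gating the whole rate (rather
than only the boundary gain) makes egocentric cells' firing
direction-selective everywhere, which is what unipolar per-wall tuning
curves require. Spikes are drawn by thinning a homogeneous Poisson
process at the declared rate bound, with position and heading
interpolated at candidate times; exceeding the bound is a contract
violation, not a silent clip. Egocentric cells are assigned to the
hemisphere contralateral to their preferred side, mirroring the
lateralization the analysis is designed to detect.

What the generator does not emulate: grooming/rearing epochs, tracking
dropouts (tests construct these explicitly), multi-field place
remapping, spike-sorting contamination, bursting, and genuinely
independent head and movement direction. Passing recovery tests
therefore demonstrates correctness of the pipeline's geometry and
statistics under its stated model, not robustness to every failure mode
of real recordings.

## Problem sizes and determinism

The calibration experiment uses 200 uniform-Poisson cells (rates drawn
1–8 Hz) on a 600 s session with 100 shuffles each; the recovery
experiment uses 10 allocentric + 10 left- + 10 right-egocentric + 20
uniform cells on a shared 1200 s session, gain/base = 10/1 Hz. The
shuffle machinery precomputes everything session-dependent once
(`ShuffleEngine`), so a border-score + stability evaluation costs about a
millisecond and both experiments together run in a few minutes on one
CPU. Every stochastic stage draws from an explicitly seeded generator;
identical configuration and seed reproduce reports byte-for-byte.

## Known limitations

- The exact published smoothing kernel, stability definition, shuffle
  counts and TRI formula live in unavailable supplementary material; the
  package uses the field-standard choices above and exposes each as a
  parameter. Absolute TRI values are therefore not comparable to
  published panel labels, only separations and fractions.
- Wall coverage is binary per bin (a bin is covered or not); a
  rate-weighted variant is a plausible alternative reading of the border
  score lineage.
- The four-wall field count uses coverage ≥ 0.25 per wall, a package
  criterion labeled as such in the summary output.
- Boundary-vector-model fitting (distance × direction receptive fields)
  and LFP analyses are out of scope.
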