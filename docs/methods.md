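# Methods

## Problem

Mice vocalize in the ultrasonic range (roughly 30–110 kHz) during social
interaction. When two animals share a platform, attributing each ultrasonic
vocalization (USV) to its emitter requires localizing the sound source in the
plane of interaction to roughly snout scale (~10–20 mm). `slimloc` implements a
time-difference-of-arrival (TDOA) method that intersects per-microphone-pair
candidate manifolds, plus the downstream analyses that such localization
enables: emitter assignment, relative-position vocalization maps, and an
embedding-based analysis of call shape.

## Localization model

**Geometry.** Microphones sit at known 3D positions (platform-centered mm,
z up, z = 0 at the platform surface) a height H above the plane in which
sources are assumed to lie (the *snout plane*, default z = 0, configurable).
Sound speed defaults to 343 m/s (dry air, 20 °C) and is configurable; it is
never estimated from data.

**Per-pair manifold.** For one pair of microphones a distance D apart (full 3D
distance), a measured arrival-time difference ΔT fixes the path-length
difference Δp = v·ΔT and hence one sheet of a hyperboloid of revolution about
the pair axis. Parameterizing by the perpendicular distance R from the axis,
the axial offset of the sheet is

    dX(R) = (Δp / 2) · sqrt((4R² + D² − Δp²) / (D² − Δp²)),

which reduces to Δp/2 on the axis (R = 0) and grows monotonically with R. With
the microphones elevated, a point of the snout plane at lateral offset y from
the pair axis has R² = y² + H_eff², H_eff being the mean microphone height
above the snout plane; sweeping y and mapping back through the pair's rotation
and translation yields the *origin curve* — the pair's locus of candidate
source positions in the snout plane. Every emitted curve point is checked
against the defining relation (3D path-difference residual < 0.1 mm), and the
closed form is validated against a brute-force locus search in the test suite.

Sign convention: `delta_t = t_j − t_i` (positive when the sound reaches
microphone j later, i.e. the source is closer to microphone i), and the curve
satisfies `dist(p, mic_i) − dist(p, mic_j) = −v·delta_t`.

**Delay estimation (EWGCC).** Both channels are band-passed to the USV band
(30–110 kHz; content above the 120 kHz anti-alias guard is always discarded),
weighted by their normalized analytic (Hilbert) envelopes so that the call-on
portion of the window dominates, mildly tapered (Tukey, α = 0.1) to suppress
window-edge transients, and cross-correlated with PHAT-style frequency
whitening (spectral floor ε = 10⁻⁸ of the cross-spectrum maximum) restricted
to the band. Two refinements matter in practice:

- *Spectral focusing.* Pure whitening assigns unit weight to frequency bins
  that carry no call energy; their random phases then contribute an error term
  independent of the noise amplitude. Each whitened bin is therefore
  re-weighted by |S|/(|S| + 0.01·max|S|), which leaves call-carrying bins
  untouched and suppresses empty ones. This restores the expected scaling of
  delay error with noise level.
- *Envelope-guided peak picking.* A narrowband call produces a correlation
  comb at the carrier period (~3.6 samples at 70 kHz / 250 kHz sampling);
  adjacent teeth differ by a few percent and a wrong pick shifts the delay by
  ~5 mm of path. The integer-lag peak is therefore taken as the raw-correlation
  maximum within ±2 samples of the correlation-*envelope* maximum, which has
  no comb. A 3-point parabola then interpolates to sub-sample resolution (ties
  break toward smaller |lag|); delays implying |Δp| ≥ D are rejected.

**Intersection.** Origin curves from all pairs (6 for 4 microphones, 3 for 3)
are rasterized on a common grid over the platform plus a 50 mm margin (cell
1 mm) as unit-height ridges with Gaussian cross-section (σ = 2 mm), via an
exact Euclidean distance transform of the rasterized polyline. The summed
density's cells at ≥ 90 % of its maximum define the peak region; the estimate
is their density-weighted centroid. The *localization accuracy* LA is 4 × the
2D RMS spread of the peak-cell centers about that centroid (floored at the
single-cell quantization spread so it stays positive). LA is a per-call
confidence measure, not the error itself; the factor 4 relates it to typical
errors.

**Per-call procedure.** Each detected call is cut into 60 ms windows advanced
by 3 ms (a single centered window, padded to 60 ms, when the call is shorter).
Windows are localized independently; those with LA ≥ 40 mm are discarded. The
final position is the per-dimension median of the kept window estimates,
projected onto the platform + margin rectangle (nearest-point projection, i.e.
per-coordinate clamping); the final LA is the median kept LA.

## Detection

The detector is a deliberately simple stand-in for a full USV detector:
per-channel spectrogram, in-band power per frame, median-across-frames noise
floor, frames > 8 dB above floor on any channel are active; active runs closer
than 10 ms merge, runs shorter than 5 ms drop. All thresholds configurable. It
assumes calls are temporally sparse (the median tracks the noise floor); a
recording that is mostly call will inflate the floor.

## Emitter assignment (mouse probability index)

Each animal's candidate source point lies on the line from its snout marker to
its head center, at fraction 0.4 for automatically tracked data (0.1 for
hand-tracked; both configurable). With localization estimate x̂ and accuracy
LA, the likelihood for animal k is

    P_k = exp(−|x̂ − x_k|² / (2·LA)²),

and MPI_k = P_k / ΣP. The exponent denominator is implemented exactly in this
printed form, (2·LA)² = 4·LA²; a `variance_mode="gaussian"` switch provides
the conventional 2·LA² reading. MPI is evaluated in log space, so it remains
exact when both raw likelihoods underflow (the case is flagged). A call is
assigned when max MPI > 0.95 *and* the estimate lies within 100 mm of at least
one animal; otherwise the exclusion reason is recorded. The track frame used
is the one nearest the call's temporal midpoint.

## Spatial vocalization maps

The receiver's position relative to the emitter is expressed in polar
coordinates centered on the emitter's snout with 0° along its head direction
(head-center → snout); left/right is mirrored onto [0°, 180°]. Default binning
is 12 × 12 over [0°, 180°] × [0, 250] mm (unspecified upstream; configurable).
Vocalization count maps are normalized bin-wise by the occupancy prior over
all video frames (bins with zero prior are masked, never infinite).
Significance per bin comes from a permutation null that redraws `n_events`
frame positions from the prior (without replacement when the prior is large
enough, with replacement — flagged — otherwise) and recomputes the density;
the two-sided p is the doubled smaller tail at resolution 1/n_perm, and the
sign marks enrichment/depletion relative to the null median. The doubled-tail
p is mildly conservative for discrete counts; calibration under the null is
verified in the tests (fraction of bins with p < 0.05 ≈ 0.05 within binomial
tolerance at 10,000 events). Property maps carry the per-bin arithmetic mean
of a call property plus a peak-normalized occupancy weight for display.

## Shape vectors and explained variance

Each call is summarized by a 203-component vector: the fundamental frequency
line (per-1-ms peak frequency of the in-band spectrum, truncated at 100 ms,
padded with its final value), its first difference (padded with zeros), the
duration (ms), the frequency directionality (mean sign of the non-zero
frequency steps — zero steps are bin quantization of slow sweeps, so they are
excluded), and the snout-to-snout distance. Wiener entropy (spectral flatness)
is the geometric-to-arithmetic mean ratio of the frame-averaged in-band
spectrum: averaging before the ratio makes a broadband noise converge to 1,
whereas averaging per-frame flatness values converges to exp(−γ) ≈ 0.56 for a
white-noise periodogram (chi²₂ bins); a `per_frame_flatness` switch exposes
the latter. Sound level is the SD of the band-passed waveform on the loudest
channel; mean energy is mean squared voltage divided by call duration (V²/s).

Vectors are z-scored per component (configurable off) and embedded in 3D with
UMAP (seeded; an established component, not re-implemented), optionally
clustered with k-means (k = 100 at full data scale). The package's own
statistic is the Local Prediction Error: each point's property is predicted as
the mean over its 5 nearest embedding neighbors with self excluded (including
self would deflate the error toward 0), and LPE is the RMSE of those
predictions. The permutation-based explained variance is

    σ²_E = 100 · (1 − LPE(X) / mean_i LPE(X_perm,i)),   i = 1..N (default 100),

with p = #(permuted LPE < original)/N, so p has resolution 1/N. A constant
property makes the ratio 0/0 and is reported as degenerate. σ²_E is invariant
to affine rescaling of the property, concentrates at 0 for properties
independent of the embedding, and exceeds 90 % for a smooth coordinate field
on a sufficiently dense cloud (≥ ~4,000 points for 5-NN; at 1,000 points the
neighbor spacing itself limits recovery to ~88 %).

## Synthetic data generator

The simulator is the ground-truth source for all validation:

- **Acoustic scenes.** A frequency-modulated chirp (default 60 → 80 kHz,
  60 ms, linear sweep, 3 ms raised-cosine ramps) is emitted from a known
  snout-plane position and rendered to each microphone by evaluating the chirp
  in continuous time at `t − dist/v` — fractional delays are exact by
  construction — scaled by 1/dist (referenced to 100 mm), plus white Gaussian
  noise at a specified per-channel in-call SNR. Byte-identical under a fixed
  seed. The 60 ms default matches the localization window; defaults lie in the
  natural USV range (30–110 kHz, 5–150 ms).
- **Interaction tracks.** Two animals follow reflecting AR(1) random walks on
  the platform (50 fps, speed 80 mm/s, head length 25 mm), with vocal events
  emitted as a Bernoulli process whose rate can be elevated inside a chosen
  (angle, distance) region — giving recoverable structure for the map
  analyses.
- **Assignment Monte Carlo.** Emitter at (0,0), receiver at (d,0) with d from
  a truncated log-normal (median 60 mm, σ_log 0.6, clipped to [5, 400] mm —
  chosen to put most mass below 100 mm, as in close courtship interaction; the
  empirical distribution is not tabulated anywhere). Localization error is 2D
  isotropic Gaussian with σ = MAE/√(2 ln 2), so the *median radial* error
  equals the stated MAE. Assignment goes to the nearer animal; the closed form
  for fixed d without filters is Φ(d/(2σ)) (only the x-component decides).
  With filters, the MPI rule (threshold 0.95, LA = σ, printed (2·LA)²
  denominator) and the 100 mm proximity rule are applied first.

### What the generator does and does not emulate

It reproduces geometric propagation delays, 1/r attenuation, additive white
noise, and position-dependent vocal behavior. It does **not** model echoes or
reverberation (the physical rig is engineered echo-free), microphone
directionality (available as an option, off by default), overlapping
simultaneous calls, amplitude/frequency roughness of natural USVs, or tracking
error. Passing tests therefore demonstrate correctness of the algorithms under
the stated acoustic model, not field performance on real recordings: an ideal
60 ms coherent chirp carries a far larger time-bandwidth product than a
typical natural call, so absolute synthetic errors (sub-mm at SNR ≥ 0 dB) are
much smaller than errors on real data.

One consequence documented here because it shapes the validation: above
roughly 20 dB SNR the localization error is limited by the 1 mm grid / 2 mm
ridge discretization (~0.15 mm), not by noise, so error medians at 40/30/20 dB
coincide up to Monte-Carlo noise and only the 20 → 0 dB portion of an SNR
sweep shows resolvable strict degradation. Likewise, dropping one microphone
of the 4-mic rig (6 → 3 origin curves) mainly fattens the error *tail* when
long coherent chirps keep the bulk of scenes at the floor; the 4-vs-3 control
is therefore run with short (10 ms) calls at 0 dB SNR — the noise-limited
regime, and short calls dominate natural duration distributions — where both
the median ordering and the paired sign test separate the arrays cleanly
(median ratio ~1.4–1.7).

## Numerical choices

- Grid cell 1 mm, ridge σ 2 mm, peak fraction 0.9 — all configurable; chosen
  well below the ~13 mm accuracy scale the method targets.
- Curves are sampled at half the grid cell in pair-frame y and resampled at
  uniform arclength before rasterization so steep segments leave no gaps.
- LA uses the unweighted RMS spread of peak cells about the density-weighted
  centroid, floored at cell/√12.
- Median over an even number of windows: midpoint of the central pair, per
  dimension independently.
- Degenerate inputs raise typed exceptions (`slimloc.errors`); unlocalizable
  calls yield a flagged result that downstream stages skip, not an exception.
- All randomness flows through `numpy.random.default_rng` seeds passed
  explicitly; UMAP and k-means receive the same seeds.

## Known limitations

- 2D only: source height is fixed to the snout plane; per-animal snout heights
  are not modeled.
- Overlapping simultaneous calls from two animals are not separated.
- The detector is a simplified stand-in and assumes sparse calls.
- Exactly two animals are supported in assignment and maps.
- The LA-vs-noise relation is non-monotone below the ridge resolution (the
  zero-noise 90 %-plateau is inflated by near-parallel ridge overlap); LA is a
  useful relative confidence measure above that scale.
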