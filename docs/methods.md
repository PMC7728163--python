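# Methods

## Pose model and reconstruction

A pose is a 5×3 matrix of landmark coordinates (nose tip, left ear, right
ear, neck base, tail base) in an arena-centred frame: origin at the arena
centre, z up, units cm. Cameras are 3×4 projective matrices calibrated by
the Direct Linear Transform: the 2-equations-per-point homogeneous system
is solved by SVD, the scale fixed by the unit-norm solution vector with a
non-negative last element. Coplanar or collinear calibration objects leave
the solution under-determined and raise an explicit calibration failure
(detected from the gap in the design matrix's singular spectrum).
Triangulation stacks the two cross-product equations per valid view
(detection likelihood > 0.5) and takes the SVD null vector; a landmark
seen by fewer than two cameras is *missing*, which is a value, not an
error.

The statistical shape model is trained on complete poses: all poses are
rigidly aligned (partial Procrustes superimposition — rotation and
translation only, no scaling, solved in closed form by the Kabsch SVD) to
the first pose, a provisional mean is computed, poses are re-aligned to
that mean (one generalized-Procrustes pass, removing the arbitrary
reference bias) and PCA is run on the flattened aligned residuals. The
first p = 3 eigenposes are kept; the sign of the first is fixed so that a
positive coefficient lengthens the nose–tail distance. Decomposition of a
pose aligns it to the mean and projects the shape residual on the
eigenposes; because the eigenposes of a trained model are orthogonal to
the rigid modes of the mean pose only up to the alignment nonlinearity,
`decompose(compose(b, R, T))` is machine-exact for constructed models and
accurate to ~1e-2 (coefficients ~1e-2 cm in pose space) for data-trained
ones at realistic shape amplitudes.

### Outlier handling

A frame is an outlier when its aligned Euclidean distance to the mean
pose (in the 15-dimensional landmark space) exceeds 5 cm or any |bᵢ|
exceeds 4√λᵢ. The coefficient bound is our choice of the unspecified
"pre-set threshold": 4 standard deviations of the training shape
distribution keeps the false-flag rate per coefficient near 6e-5 per
frame while catching mis-reconstructions that deform the body plausibly
in distance but implausibly in shape.

Frames with at most two bad landmarks are rebuilt. The trustworthy
subset is the 3-landmark subset whose rigid fit of the mean-pose subset
has the smallest residual (all C(5,3) = 10 subsets are scored). The
shape coefficients of the frame are re-estimated by piecewise cubic
Hermite interpolation (PCHIP) of the neighbouring clean frames'
coefficient series. The final rigid transform aligns the
*shape-informed* model subset (mean + interpolated shape) to the
observed subset rather than the bare mean subset: for strongly elongated
or bent (but correct) poses, aligning the straight mean skews the
rebuilt landmarks by the shape difference itself, while the
shape-informed alignment leaves correct frames essentially untouched.

### Refinement

Each frame minimizes

    C(b, R, T) = ‖X_obs − ((X̄ + Σ bᵢPᵢ) R + T)‖²_F + α Σ bᵢ²/λᵢ

with α = 0.001. Two numerical choices define the cost precisely: the data
term is the residual between the observed pose and the model-generated
pose (the only form under which the cost vanishes at the truth), and the
norm is squared so that the two alternating steps —
closed-form Procrustes for (R, T) at fixed b, ridge projection
bᵢ = ⟨Pᵢ, X_aligned − X̄⟩ / (1 + α/λᵢ) for b at fixed (R, T) — are each
exact minimizers, guaranteeing monotone descent. Iteration stops when the
cost change falls below 1e-8 or after 100 iterations (non-convergence is
flagged, best-so-far returned). The penalty sum runs over the p = 3
coefficients that exist.

With isotropic landmark noise the refinement can only remove the noise
component orthogonal to the 9-dimensional pose manifold (3 shape + 6
rigid degrees of freedom of 15), a variance factor of 9/15; the temporal
smoothing pass (kernel [0.2, 0.6, 0.2] on every element of b, R and T,
edge frames renormalized, each smoothed R projected to the nearest
rotation by SVD with det forced +1) removes a further ≈0.56 of the
remaining variance. Together they put the refined landmark RMSE at
roughly 0.5–0.6× the raw triangulated RMSE on the synthetic rig.
Smoothing runs after refinement.

## Measures

Nine measures per frame. rear: z of the head centroid (mean of nose and
both ears), cm. elongation: b₁ (sign convention above). bend: b₂, signed;
a magnitude variant is a caller-side `abs`. locomotion: ‖ΔT_xy‖·fps,
cm/s. rotation: |Δyaw|·fps, deg/s, yaw taken from the body x-axis image
projected on XY. freezing: the fraction of a centred 0.33-s window whose
mean landmark speed is below 0.5 cm/s — a windowed immobility measure
for which no canonical closed form exists; the window and threshold are
config-exposed (`RunConfig.freeze_window_s`, `freeze_speed_cms`). The
three Δ measures are absolute first differences × fps (plotted magnitudes
are nonnegative). Outlier frames propagate NaN.

Quantile normalization pools each measure over all frames × trials and
maps value → (rank−1)/(N−1) with ties averaged: the continuous limit of
equal-count interval binning (with the interval count taken to its
continuum limit), deterministic, order-preserving and idempotent. Constant
measures map to 0.5 with a warning.

Initial positions are allocentric: head elevation = vertical angle of the
neck→nose vector, azimuth = its XY direction (0° = +X axis), head
position = nose/neck midpoint.

## Ensemble statistics

Response divergence: RD = (D − ⟨D_sh⟩)/⟨D_sh⟩ with D the Euclidean
distance between group-mean time series and D_sh from 1000 label
shuffles; significant when D > D_sh in more than 95% of shuffles.

Bi-cross-validation rank: rows and columns are split into h = l = 2
random groups (2×2 by default; it maximizes the
held-out blocks' size at this trial count) and each held-out block A is
predicted as B(D̂ₖ)⁺C with D̂ₖ the SVD truncation; errors are averaged
over 10 random repartitions and the rank is the argmin over k.

Specificity index: weights wᵢⱼ = 1/distᵢⱼ over the k nearest neighbours.
Coincident points take the full weight in the 1/d limit (SI over the
zero-distance neighbours only), preserving continuity.

Decoding: PCA is fit on training folds only (avoiding train/test leakage), stratified 10-fold CV, repeated with
reshuffled folds. KNN is implemented directly because its tie-break
(the nearest neighbour among tied classes decides) is part of the
contract; the forest decoder is a standard random forest with trees
capped at 20 leaf nodes, tree counts from {10, 20, 40, 80, 160, 320}.

## Mutual information and clustering

Clustering is k-means++ (best of 100 runs per repeat, 50 repeats; library
backend). Plugin MI = H(G) − H(G|S) from frequency histograms. The
limited-sampling bias is removed by quadratic extrapolation: plugin MI on
the full sample, on random disjoint halves and quarters (averaged within
each split, 20 random splits), a quadratic fit in 1/N, read off at
1/N → 0. The corrected value is clipped at zero for reporting with the
raw extrapolation retained. For independent labels at n = 516, |G| = 7,
|S| = 3 the plugin bias sits near the Miller–Madow term
(R−1)(C−1)/(2N ln 2) ≈ 0.017 bits and the corrected estimate within
±0.05 bits of zero.

MI(k) = a(1 − e^(−k/τ)) + bk is fitted by bounded nonlinear least squares
(a, b, τ ≥ 0), multi-started from 5 perturbations of (max MI, tail slope,
τ = 3) to avoid the a/τ exchange degeneracy. τ is reported as the size of
the high-gain region; selecting a single integer cluster count from it is
left to the user.

Cluster refinement removes, per cluster, the fraction of members farthest
from the centroid (≤ 0.5, never emptying a cluster) and reports
silhouette and inertia before/after.

Initial-position MI: every per-dimension partition-count array (5
dimensions, ≤ 8 partitions each, product ≤ 20) defines equal-count bins;
MI is estimated per scheme and the least-squares line of MI against
1/#partitions is extrapolated to zero. The max-match control sorts the
binned positions and the cluster labels independently so the two
sequences agree maximally before the same estimate runs — an upper bound
that recovers ≈98% of H(G) at n = 516 and is the appropriate check that a
one-to-one mapping would be visible. A line over *all* schemes cannot
extrapolate a mapping carried by a single dimension to H(G), because
schemes that spend partitions on uninformative dimensions dominate the
fit; the data-driven estimate is therefore interpreted jointly with the
max-match bound.

## Primitives and sequence models

The epoch from 0.33 s before stimulus onset to 2 s after is tiled into
windows of one of six durations (0.133, 0.2, 0.333, 0.4, 0.666, 1.0 s —
whole frame counts at 15 Hz; the grid check tolerates the decimal
rounding of 2/15 and 10/15); windows are clustered into 2–10 primitives
and each trial
becomes a symbol string. Pre-onset windows supply Markov context but are
excluded from decoding likelihoods by default (config-switchable).

The per-stimulus sequence model is PPM with method-C escapes and
exclusions: at each context level the escape probability is t/(n+t)
(t distinct symbols seen, n total count, both after excluding symbols
already credited at longer contexts); when every remaining candidate has
been seen at a level the escape is suppressed and the level's counts are
renormalized — this closure is what makes every predictive distribution
sum to one exactly (property-tested). The bottom level is uniform over
unexcluded symbols, so no sequence has zero probability. Decoding takes
the maximum-likelihood model; ties are broken by model order and flagged.
Hold-out evaluation uses stratified 10-fold CV.

## Synthetic ground truth

The generator is the package's study-conditions oracle. The mean pose is
mouse-like (nose–tail ≈ 8 cm); the three designed eigenposes (elongation,
lateral bend, head raise) are projected orthogonal to the 6 infinitesimal
rigid modes of the mean pose before orthonormalization — otherwise part
of each deformation would be absorbed by the Procrustes alignment and the
learned subspace could not match the generating one. Eigenvalues follow
the 43:31:17 variance proportions with 1 cm² total shape variance (±2 SD
of elongation ≈ ±1.4 cm on an 8 cm body). Four overhead cameras at the
corners of a 30×30 cm arena (60 cm high, f = 1400 px, 1280×1040 images)
view every simulated pose in-frame. Motifs are parameterized directly in
(b, R, T) space — run (10 cm/s, wall-reflecting), rear (oscillating head
raise), freeze-straight, freeze-bent, turn (180 deg/s) — with amplitudes
within ~3 SD of the shape distribution so correct motif frames are not
flagged as outliers. Corruption is modelled at three levels: Gaussian
pixel noise, isotropic 3D landmark jitter before projection (the
well-defined meaning of "landmark noise in cm" for a multi-camera rig),
and planted gross mis-detections (a landmark displaced 10 cm with high
confidence) whose bookkeeping is returned as ground truth.

Trial ensembles default to the study scale: 516 trials, 172 per stimulus
(flash/loom/sound), 30 response timepoints × 9 measures, a 3×7
stimulus→cluster mixing in which each stimulus reproducibly evokes 2–3
preferred clusters, smooth sigmoid templates with cluster-specific
levels/latencies, Gaussian noise σ = 0.05 on the normalized scale, and
closed-form MI of the planted joint. A variant
(`shared_locomotion_spec`) makes the locomotion channel degenerate across
cluster groups so that the full measure set carries stimulus information
locomotion cannot resolve — the generator behind the τ-ordering analysis.

What the generators do not emulate: real landmark detectors' structured,
pose-dependent failure modes; correlated multi-camera occlusions; animal
identity effects and session-level drift; and any real relation between
initial positions and responses. Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated noise models,
not performance on recorded video.

## Problem sizes

Tests and examples scale iteration counts, not study conditions:
ensembles stay at 516 trials, while MI(k) curves use k = 2..12 with 6
clustering repeats × 15 k-means initializations, and decoding repeats are
reduced. These are algorithmic effort knobs; estimates are unbiased in
them, only slightly noisier.

## Known limitations

- The freezing measure is one defensible windowed-threshold reading of
  behavioral immobility, and its parameters matter for
  absolute freeze values (not for motif orderings at the defaults).
- Bend is kept signed; analyses that want magnitude must take |b₂|.
- The refinement's data term weights all landmarks equally
  (no per-landmark anisotropic noise model).
- The PPM models are batch-trained from context counts; adaptive
  (online) PPM would give slightly different escape estimates early in
  training.
- Rank estimation by BCV assumes homoscedastic noise across the matrix;
  heteroscedastic measures may bias the argmin.
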