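# ethopose

3D reconstruction of mouse body poses from multi-camera landmark tracks,
and a statistics suite for quantifying how specific, diverse and
structured sensory-evoked defensive behaviors are.

`ethopose` is aimed at behavioral neuroscientists who track a small set of
body landmarks (nose, ears, neck base, tail base) with a markerless
tracker such as DeepLabCut across several calibrated cameras, and want to
go from per-camera 2D tracks to a compact, denoised description of posture
and movement — and from there to population-level questions: do different
stimuli (a light flash, an overhead looming disc, a loud sound) evoke
distinguishable behaviors? How many distinct behaviors does one stimulus
evoke? What sub-second action primitives compose them?

## The model

Each frame's pose `X(t)` (a 5×3 matrix of landmark coordinates, cm) is
described by a statistical shape model:

    X(t) = (X̄ + Σᵢ Pᵢ bᵢ(t)) R(t) + T(t)

where `X̄` is the mean pose, `Pᵢ` are *eigenposes* (principal directions
of body-shape change learned by PCA on rigidly aligned poses; the first
two capture body elongation and lateral bending), `bᵢ` are shape
coefficients, and `R, T` encode the animal's position in the arena.
Raw 3D poses come from DLT camera calibration and least-squares
triangulation of landmarks whose detection likelihood exceeds 0.5;
outlier poses (aligned distance to the mean > 5 cm, or shape coefficients
out of bounds) are rebuilt from their trustworthy landmark subset, and a
regularized refinement minimizes

    ‖X_obs − (X̄ + Σᵢ Pᵢ bᵢ) R − T‖² + α Σᵢ bᵢ²/λᵢ ,   α = 0.001

per frame, followed by temporal smoothing with the kernel [0.2, 0.6, 0.2].

From the refined parameters, nine measures are computed per frame — three
postural (rear = head height, elongation = b₁, bend = b₂) and six
movement (locomotion, freezing, rigid rotation, and the rates of change
of the postural three) — quantile-normalized to [0, 1].

On trial ensembles the package provides: shuffle-normalized response
divergence; bi-cross-validation matrix rank estimation; an
inverse-distance-weighted specificity index
`SIᵢ = Σⱼ wᵢⱼ 1[Yᵢ=Yⱼ] / Σⱼ wᵢⱼ` over the k nearest neighbour responses;
KNN and random-forest stimulus decoding; k-means++ behavioral clustering
with bias-corrected mutual information and the curve fit
`MI(k) = a(1 − e^(−k/τ)) + bk`; PPM variable-order Markov models over
clustered sub-second primitives; and an extrapolation of
MI(initial position; response cluster) to infinitely many partitions.

Every generator in `ethopose.synthetic` carries analytic ground truth
(planted subspaces, planted cluster joints with closed-form MI, Markov
chains with computable Bayes accuracy), so the whole pipeline is testable
end to end without any recorded data.

## Worked example

```sh
python examples/behavior_clustering.py
```

```
planted clusters: 6, analytic MI = 1.110 bits

full set (270 dims):
  k :     2     3     4     5     6     7     8     9    10    11    12
  MI:  0.28  0.37  0.59  0.85  1.07  1.07  1.07  1.07  1.06  1.07  1.07
  fit: a=1.30, b=0.0000, tau=5.43

locomotion (30 dims):
  k :     2     3     4     5     6     7     8     9    10    11    12
  MI:  0.16  0.21  0.19  0.20  0.20  0.19  0.19  0.18  0.18  0.18  0.19
  fit: a=0.19, b=0.0000, tau=0.85
```

The ensemble plants 6 behavior clusters whose locomotion channel can only
distinguish 3 profiles. Clustering the full 9-measure response recovers
the stimulus information in steps up to k = 6 and then flattens — the
"high-gain / low-gain" break at the true cluster count, with the MI
plateau matching the analytic 1.11 bits. The locomotion-only projection
saturates at a third of that information and a much smaller rise constant
τ: the extra postural measures carry stimulus information that locomotion
alone cannot resolve.

Other examples follow the same pattern, one capability each:
`reconstruct_track.py` (calibration → triangulation → refinement; prints
raw vs refined landmark RMSE), `behavior_measures.py` (the 9 measures per
motif), `stimulus_specificity.py` (response divergence, SI, KNN
decoding), `primitives_vmm.py` (primitive extraction and PPM decoding),
`initial_positions.py` (initial-position MI extrapolation with its
max-match control).

A thin CLI mirrors the main entry points
(`ethopose calibrate|reconstruct|stats|cluster|vmm|synth`); the Python
API is the primary interface.

## Layout

- `src/ethopose/geometry3d.py` — DLT calibration, triangulation
- `src/ethopose/shape_model.py` — Procrustes alignment, SSM training,
  outlier correction, refinement, smoothing
- `src/ethopose/features.py` — the 9 measures, quantile normalization,
  eigenpose descriptors, initial positions, epochs
- `src/ethopose/stats.py` — response divergence, BCV rank, specificity
  index, decoders
- `src/ethopose/infocluster.py` — clustering, bias-corrected MI, MI(k)
  curve fit, cluster refinement, initial-position MI
- `src/ethopose/vmm.py` — primitives, PPM models, sequence decoding
- `src/ethopose/synthetic.py` — ground-truth generators
- `src/ethopose/io.py`, `config.py`, `pipeline.py`, `cli.py` — formats,
  configuration, the end-to-end driver and the CLI
- `docs/methods.md` — modeling choices, parameters and limitations
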