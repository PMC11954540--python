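# Methods

## Model

`octad` detects out-of-distribution retinal structure by reverse
teacher–student knowledge distillation. A frozen convolutional teacher *T*
maps a B-scan X ∈ R^{H×W} to an N-level feature pyramid F_n^T with shapes
(C_n, H/s_n, W/s_n) fixed by an `EncoderSpec` (default N = 3,
C = (16, 32, 64), s = (4, 8, 16)). A trainable bottleneck *B* average-pools
every level to the deepest resolution, projects each with a 1×1 convolution,
concatenates and fuses them into a narrow code F^B (default C_N/4 = 16
channels). A trainable student decoder *S* starts from F^B and works
deepest-to-shallowest (1×1 reduce, 3×3 refine, nearest-neighbour upsample,
1×1 head per level), emitting F_n^S with exactly the teacher's shapes.

The per-position disparity is the weighted sum of cosine and Euclidean
distance,

    D(f_t, f_s) = λ (1 − f_t·f_s / max(‖f_t‖‖f_s‖, ε)) + ‖f_t − f_s‖₂

with λ = 1 (the cosine term only is weighted) and ε = 1e-8, and the training
loss is the per-level spatial mean of D summed over levels. Training on
normal B-scans only teaches S+B to replicate the teacher on normal anatomy;
the narrow code prevents anomalous feature content from surviving the
round-trip, so D lights up on lesions at test time.

Assumptions: anomalies are local appearance/structure deviations visible to
2-D convolutional features; each B-scan is independent (no inter-slice
modelling); a frozen random teacher provides sufficiently diverse features
at desk scale (a saved encoder checkpoint can be substituted via
`pretrained_source`).

## Key parameters

| parameter | default | role |
|---|---|---|
| `EncoderSpec.channels` / `strides` | (16,32,64) / (4,8,16) | pyramid shapes; strides must be power-of-two multiples |
| `EncoderSpec.kernel_size` | 5 px | teacher receptive field; 5×5 resists speckle better than 3×3 |
| `EncoderSpec.input_smoothing_sigma` | 1 px | Gaussian despeckling before per-image min-max normalisation; part of the model contract, applied identically at train and test time |
| `EncoderSpec.code_channels` | C_N/4 = 16 | bottleneck width; the compression that creates the anomaly gap |
| student width factor | 0.75 of teacher channels | low replication noise on normals while keeping parameters strictly below the teacher (38.7k vs 67.5k) |
| `DistanceConfig.lambda_weight`, `epsilon` | 1, 1e-8 | distance metric |
| `TrainConfig` | 15 epochs, batch 16, Adam lr 5e-3 | optimisation; `learning_rate=0` is a valid null step |
| `ScoreConfig.aggregation_rule` | max | P in the B-scan score Σ_n P(M_n) |
| `ScoreConfig.gaussian_sigma` | 4 px | anomaly-map smoothing at input resolution (0 disables) |
| `ScoreConfig.score_source` | per_level_raw | score from raw level maps; `composed_map` (P on the resized+smoothed map) is available for ablation — at desk scale the two were indistinguishable |

Numerical choices: corner-aligned bilinear resampling (output corners map
exactly onto input corners) pinned by an oracle test; maps are never
rescaled to [0, 1], so the severity threshold lives on raw map values; the
optimal ROC cutoff breaks ties toward the higher threshold (fewer flagged);
undefined PPV/NPV ratios (zero denominator) are reported missing and
excluded from summary means with counts; severity `map_score` is 0 when no
map value exceeds the threshold; single-class leave-one-out training folds
are skipped with a warning. All networks run in float64; fixed seeds make
simulation, training and scoring bit-reproducible on one machine. A single
global seed fans out as child(seed, k) = (seed·1000003 + k) mod 2³¹.

## Phantom generator

The phantom emulates fovea-centred OCT volumes at the level the detector
needs: n_layers horizontal reflectivity bands — defaults
(0.35, 0.15, 0.45, 0.25, 0.65), the bright/dark alternation of
NFL/plexiform/nuclear/photoreceptor/RPE — between smooth random boundaries
(correlation length 12 px laterally, smooth along the slice axis, amplitude
≈ 0.08·H), a dim noisy background (0.05) above and below the stack, and
unit-mean multiplicative gamma speckle (shape 10; ∞ disables). Default
geometry is 64×64 with 8 B-scans per volume (25 training volumes = 200
slices); 496×512 is available for realistic-geometry runs.

Lesions are area-calibrated so masks land within ±20% of `target_area`
(discretised shapes cannot hit it exactly): bumps are semi-elliptic boundary
elevations with bright fill (drusen/PED-like), fluid pockets are 2:1
hypo-reflective ellipses (IRF/SRF-like), deformations are Gaussian vertical
warps of the whole stack whose mask is the displacement super-level set.
The deformation peak amplitude is max(10, 0.16·H) px — deliberately above
the normal boundary-perturbation envelope (≈ 0.08·H), because a warp inside
that envelope would be a sample from the normal distribution, not a lesion.
Anomalous volumes place one lesion per slice on the central half of the
slices (disease concentrated near the fovea), kinds cycling, areas
log-uniform over 100–1600 px².

What the phantom does **not** model: A-scan physics (shadowing, attenuation,
vessel artifacts), device-specific noise calibration, curved retina/fovea
pit geometry, real lesion texture. Passing tests therefore demonstrate that
the mechanism — normal-only distillation producing discriminative,
localised disparity maps — works end-to-end, not that clinical-grade
performance transfers to any particular scanner or cohort.

## Design choices

- **Frozen random teacher by default.** No pretrained natural-image encoder
  is bundled; randomly-initialised frozen teachers are an accepted variant
  of distillation-based anomaly detection and keep the package
  self-contained. The `pretrained_source` hook accepts a saved encoder.
- **Despeckling in the input contract.** With a random teacher, raw speckle
  dominated the feature disparity; a 1 px Gaussian before normalisation
  makes features respond to structure. It is stored in the checkpointed
  spec so train/test preprocessing can never diverge.
- **Wide student, narrow code.** A 0.5-width student under-fit normal
  variation and its replication noise set the detection floor. Widening to
  0.75 (still ~43% fewer parameters than the teacher) and narrowing the
  code to 16 channels moved the anomaly gap from "student can't replicate
  anything well" to "student replicates normals well but anomalies cannot
  pass the code" — the intended mechanism. Chosen after comparing
  detection across three independent teacher initialisations.
- **Score from raw level maps.** The scalar score aggregates the raw M_n
  (per-level max, summed), not the composed map, keeping the score
  independent of resize/smoothing settings; the alternative is one flag away.
- **Data-driven severity threshold.** The activation threshold for severity
  scoring is the pixel-weighted mean anomaly-map value over normal training
  volumes (`training_threshold`), replacing any hard-coded constant.

## Evaluation battery and problem sizes

`scripts/acceptance.py` and the test suite run the full study at desk
scale: 25 normal training volumes (200 slices of 64×64), 20 training
epochs, 25 held-out normal + 25 lesioned volumes (400 test slices, 100 of
them lesioned). Reported quantities: B-scan and volume ROC AUC and AP,
Spearman/Pearson severity correlations over the 100 lesioned slices,
fraction of lesioned slices whose mean map value inside the 4-px-dilated
mask exceeds the outside mean, and leave-one-volume-out PPV/NPV over the 25
lesioned (mixed-slice) volumes. A full run takes ~30 s on one CPU core.

## Known limitations

- Pure-NumPy networks are desk-scale: 496×512 volumes score fine but
  training at that resolution is slow; the architecture caps at
  power-of-two stride ladders and odd square kernels.
- The anomaly maps localise but do not segment; mask-level Dice is out of
  scope, matching the method's screening intent.
- Small smooth deformations remain the hardest lesion class — their
  per-slice AUC trails bumps and fluid pockets, mirroring the general
  finding that detection difficulty tracks lesion size and subtlety.
- Scores are not calibrated probabilities; cross-cohort comparison requires
  a reference normal set (e.g. via `training_threshold` or the
  leave-one-out cutoff transfer).
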