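# spixseg

Weakly supervised brain-tumor segmentation for multimodal 2-D MRI: learn
pixel-level masks when the only annotation is a per-slice bit saying
"contains tumor".  Aimed at researchers who have image-level labels (cheap)
but not contours (expensive) and want segmentation-quality output plus the
evaluation conventions to judge it.

## Method

Three stages, trained on 4-channel slices (T1, post-contrast T1, T2,
T2-FLAIR):

1. **Classifier** — a CNN estimates `P(tumor | x)` from the binary labels.
2. **Saliency seeds** — randomized input sampling perturbs each slice with
   K shared random masks and accumulates the classifier's scores into a
   saliency map `H(p) = (1/Kp̄) Σᵢ scoreᵢ·maskᵢ(p)`.  The top 20% of pixels
   become positive seeds `S₊`, the bottom 20% negative seeds `S₋`; slices
   the classifier calls healthy are overridden to all-negative seeds.
3. **Deep superpixels** — a fully convolutional generator emits a soft
   association map `Q ∈ Δ^{N_S}` per pixel and a clustering network scores
   each superpixel, `R ∈ Δ^{N_S}` per image.  Both train jointly against

       L = L_spixel + α·L_seed,   α = 50,

   where `L_spixel` pulls each pixel toward its association-weighted
   superpixel mean in intensity and position (size coefficient m = 3/160)
   and `L_seed = −[Σ_{S₊} log H₊ + Σ_{S₋} log(1−H₊)]/(|S₊|+|S₋|)` with
   `H₊(p) = Σ_s Q[s,p]·R[s]`.  Thresholding `H₊` (threshold chosen on
   validation Dice) gives the final mask; classifier-predicted-healthy
   slices get empty masks.

Evaluation: smoothed Dice `(2|A∩B|+1)/(|A|+|B|+1)`, directed HD95 (95th
percentile of boundary distances, 0 for empty masks), and U-Dice
`(|A∩B|+1)/(|A|+1)` — the undersegmentation score a seed should maximise.

Everything trains on a compact numpy autodiff engine shipped in
`spixseg.nn` (conv/batch-norm layers, Adam, LR schedules), so the package
has no deep-learning framework dependency.  A synthetic phantom generator
(4 correlated channels, elliptical bright lesions, evaluation-only masks)
provides datasets so the full pipeline runs without downloads; BraTS-style
NIfTI volumes load through `spixseg.data.read_nifti_volume` with the
standard preprocessing (foreground crop, 1–99 percentile clip, min-max
scaling, axial slicing dropping 30 end slices, 128×128 patches).

## Worked example

```python
import json
from spixseg.pipeline import RunConfig, run_pipeline

cfg = RunConfig.desk_scale(out_dir="runs/demo", rng_seed=0)
summary = json.loads((run_pipeline(cfg) / "summary.json").read_text())
print(summary)
```

Desk scale means 256/32/64 train/val/test phantom slices of 32×32, small
backbones, 512 occlusion masks — several minutes on one CPU.  Output:

```
{"threshold": 0.3,
 "classifier_test_accuracy": 0.984375,
 "mean_test_dice": 0.9776242156969217,
 "mean_test_hd95": 0.321875,
 "mean_test_u_dice": 0.9753957554433619,
 "all_positive_baseline_dice": 0.2033571476719003,
 "mean_effective_superpixels": 11.875}
```

Read: the classifier got 63 of 64 test slices right; thresholding the soft
superpixel clusters at 0.3 yields mean Dice 0.978 against the phantom
reference masks (healthy slices score 1 when correctly gated empty), far
above the 0.203 of segmenting everything; mean boundary error is a third
of a pixel; and only ~12 of the 64 candidate superpixels end up owning
pixels.  Notably the masks are much better than the raw saliency seeds
that supervised them (seed Dice ≈ 0.5) — the intensity-compactness loss
snaps superpixel boundaries onto the lesion.  `examples/` holds one narrative script per capability,
and the `spixseg` CLI (`phantom`, `train-classifier`, `make-seeds`,
`train-superpixels`, `infer`, `evaluate`, `run-all`) wraps the same
library calls for shell use.

At full scale (`RunConfig.paper_scale()`: 128×128 slices, VGG-16-bn /
ResNet-18, K = 4000, 100 epochs) the same code reproduces the published
protocol's configuration; reference results at that scale were reported as
Dice ≈ 0.69–0.75 on real multi-institutional cohorts, which desk-scale
phantom numbers neither match nor claim to.

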