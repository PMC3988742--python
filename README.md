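# vesselsnake

Segmentation of blood vessels in contrast-enhanced images with a localized
region-based active contour that (a) adapts the size of its local statistics
window to how "blood-like" the contour interior looks, and (b) suppresses
leakage into adjacent bright structures with a nonparametric tubular shape
prior.  The package ships a synthetic phantom generator with exact ground
truth, the segmentation engine, evaluation metrics, and a CLI, so the whole
method is exercisable and testable end to end without any clinical data.

## The problem

Contrast-enhanced CT angiography renders the blood pool bright, but vessel
boundaries are often weak (distal, thin segments) and vessels run tangent to
other bright structures (chambers, veins).  A purely intensity-driven
contour either stops short of faint segments or *leaks* through an
intensity-ambiguous gap and floods the neighboring structure.

## The model

The contour is the zero level set of a signed distance function φ (positive
inside).  Each side of the contour is modeled locally by a Gaussian
N(μᵢ(x), σᵢ²(x)) estimated over the ball window Ω_x of per-point radius
r(x), and φ follows the gradient flow

    ∂φ/∂t = δ_ε(φ) [ μ·div(∇φ/|∇φ|) + log(p₁/p₂) − λ·S(x) ]

with three ingredients:

* **Local Gaussian data term** — log(p₁/p₂) is the log Bayes factor of the
  point's intensity under the interior vs exterior windowed Gaussians
  (clipped for robustness).
* **Adaptive window radius** — a K-component Gaussian mixture fitted to the
  global histogram by EM identifies the blood-pool mode (μ_b, σ_b²); the
  window radius follows the Bhattacharyya distance D_B between the local
  interior Gaussian and the blood pool:

      r(x) = min_scale + max_scale · exp(−τ·D_B),
      D_B  = ¼ ln(¼(σ₁²/σ_b² + σ_b²/σ₁² + 2)) + ¼ (μ₁−μ_b)²/(σ₁²+σ_b²)

  Blood-like interiors get large, noise-robust windows; deviating interiors
  (weak local contrast) get small, sensitive ones.
* **Tubular shape prior** — around every interior voxel the image is sampled
  on a circle (2D) / sphere (3D) of radius R in n directions; the Shannon
  entropy H of the normalized profile scores how dispersed the surrounding
  bright structure is, rescaled to the vesselness v = 2H/ln(n) − 1 ∈ [−1,1].
  A tube concentrates the profile into two (or, at a bifurcation, three)
  short arcs → low v; a blob interior is flat → v → +1.  Voxels whose v
  exceeds the ideal-tube calibrated neutral score v₀ exert the erosion
  pressure S(x) (a windowed hinge integral), which is what pushes the
  contour back out of leak regions.

Evaluation uses the voxel-overlap metrics TP = |B∩R|/|R|,
FP = (|B|−|B∩R|)/|R|, OM = 2|B∩R|/(|B|+|R|) (Dice) and the symmetric
Hausdorff distance between marching-squares/cubes surface vertices.

## Worked example

Segment the classic leak scenario — a noisy tube with a tangent bright blob
of identical intensity — with the plain localized Chan–Vese baseline and
with the full model:

```python
from vesselsnake import (PhantomSpec, make_phantom, fit_histogram_gmm,
                         evolve, EnergyParams, evaluate)
from vesselsnake.evolution import baseline_params
from vesselsnake.phantoms import default_seed_mask

spec = PhantomSpec(shape=(128, 128), geometry="straight_plus_blob",
                   noise_sigma=25.0, rng_seed=0)
image, truth = make_phantom(spec)
model = fit_histogram_gmm(image, n_components=3, seed=0)
print(f"blood pool: mean={model.blood_mean:.1f}, sigma={model.blood_variance**0.5:.1f}")

seed = default_seed_mask(spec)
full = evolve(image, seed, model=model, params=EnergyParams())
base = evolve(image, seed, model=model, params=baseline_params(EnergyParams()))
for name, res in (("localized CV baseline", base), ("full model", full)):
    rep = evaluate(res.mask, truth)
    print(f"{name}: TP={rep.TP:.3f} FP={rep.FP:.3f} OM={rep.OM:.3f} "
          f"Hausdorff={rep.hausdorff:.1f} vox ({res.iterations} iterations)")
```

Output:

```
blood pool: mean=99.0, sigma=25.3
localized CV baseline: TP=1.000 FP=0.450 OM=0.816 Hausdorff=24.0 vox (687 iterations)
full model: TP=0.946 FP=0.014 OM=0.966 Hausdorff=4.0 vox (800 iterations)
```

The baseline floods the tangent blob (false-positive fraction 0.45 of the
vessel size, worst boundary error 24 voxels — the blob's far edge); the
shape-constrained model confines the contour to the vessel (FP 0.014, Dice
0.966).  The same comparison is available from the shell:

```
vesselsnake phantom --geometry straight_plus_blob --noise 25 --seed 0 \
    -o img.png --truth gt.png --seed-mask seed.png
vesselsnake segment -i img.png --seed-mask seed.png -o mask.png --trace energy.csv
vesselsnake evaluate --pred mask.png --truth gt.png --report report.json
vesselsnake bench --lambdas 0,0.2,0.4,0.8 --out sweep.csv   # λ sweep
```

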