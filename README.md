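# liverseg

Semi-automatic segmentation of liver-like regions in 2-D grayscale
(abdominal-CT-style) images, built around a seeded **GrowCut** cellular
automaton with a Gaussian-kernel energy function and an active-contour
(**snake**) refinement stage driven by **gradient vector flow** (GVF).

The intended user marks a few foreground strokes inside the organ and a
loose background stroke around it; the pipeline does the rest:

1. **Wavelet denoising** — multi-level 2-D decomposition with either
   zeroed or soft-thresholded detail bands,
   `W ← sgn(W)·(|W|−λ)` for `|W| ≥ λ`, else 0.
2. **K-means ROI pretreatment** — cluster the gray values
   (minimising `J = Σ_j Σ_{n∈S_j} |x_n − μ_j|²`), keep the largest
   non-background connected region, fill its holes, and crop to its padded
   bounding box.  This shrinks the automaton's domain without changing its
   result.
3. **Seeded GrowCut** — each pixel holds a label `l_p`, a strength
   `θ_p ∈ [0,1]` and its gray value `C_p`.  A labeled neighbour `q`
   captures `p` when `g(C_p, C_q)·θ_q > θ_p`.  Two energies are provided:
   the classic linear similarity `g = 1 − |C_p − C_q| / max‖C‖`, and the
   Gaussian-kernel energy
   `B_{p,q} = exp(−(I_p − I_q)² / 2σ²) · 1/dist(p,q)`,
   which builds decisive barriers at weak edges and penalises diagonal
   attacks.  An optional smoothing extension (enemy thresholds T1/T2)
   suppresses boundary burr.
4. **GVF-snake refinement** — the GrowCut boundary becomes a closed
   contour `x(s)` minimising
   `E = ∫ ½(α|x′|² + β|x″|²) + E_ext(x(s)) ds` with
   `E_ext = −|∇(G_σ * I)|²`, evolved semi-implicitly against the GVF field
   `w = (u, v)` that minimises
   `∬ μ|∇u|² + μ|∇v|² + |∇f|² |w − ∇f|² dx dy`.

Agreement is scored with the Dice-style overlap
`precision = 2|S₁∩S₂| / (|S₁|+|S₂|)`.

A deterministic **phantom generator** produces synthetic abdominal slices
(dominant quasi-elliptical liver, similar-intensity adjacent organ, fuzzy
blurred edges, additive noise) with exact ground truth and auto-placed
seeds, so the whole pipeline is testable without clinical data.

## Worked example

```bash
liverseg phantom --difficulty fuzzy_edge --seed 7 --out-dir fx/
liverseg run --seeds fx/seeds.csv fx/image.png out.png
liverseg evaluate out.png fx/truth.png
```

prints (GrowCut progress log omitted):

```
precision=0.9756
```

meaning the refined full-pipeline mask overlaps the phantom's ground-truth
liver ellipse with Dice 0.976 on a fixture whose boundary was blurred with
a σ=3 Gaussian.  The same comparison programmatically:

```python
from liverseg import phantom, pipeline, metrics

image, truth, seeds = phantom.generate(phantom.make_spec("fuzzy_edge", seed=7))
mask, report = pipeline.segment(image, seeds, pipeline.kigc_snake_config())
print(metrics.precision(mask, truth))        # 0.9754...
print(report["roi"]["bbox"])                 # (12, 20, 116, 104)
print(report["growcut"]["iterations"])       # 75
```

Three preset configurations mirror the method ablations: `tgc_config()`
(traditional energy, full frame), `kigc_config()` (K-means ROI + improved
energy) and `kigc_snake_config()` (the full method).
`pipeline.compare_runs` tabulates their Dice, iteration counts, visited
cells and boundary smoothness on any image with ground truth.

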