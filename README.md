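# midirseg

Small-target segmentation for mid-infrared monitoring video.

Long-range thermal surveillance (grassland monitoring, perimeter watching)
produces low-contrast grayscale video in which the objects of interest —
grazing animals, people — occupy only tens of pixels and move
intermittently. Classic per-pixel background modelling fails in a
characteristic way here: while a target dwells, its interior intensity is
absorbed into the background model and the detections develop
false-negative holes (the *stay-hole* problem). `midirseg` implements a
hybrid pipeline that addresses this:

1. **ITF-GMM** — a per-pixel Gaussian-mixture background model whose
   temporal behaviour adapts to the video. Each pixel *m* is modelled as
   `p(m_t) = Σᵢ ωᵢ,ₜ η(m_t; μᵢ,ₜ, σᵢ,ₜ²)`; a value matches a component when
   `|m_t − μᵢ,ₜ₋₁| ≤ 2.5 σᵢ,ₜ₋₁`, matched components are updated with
   learning rate α (`ω ← (1−α)ω + α`, `μ ← (1−ρ)μ + ρ m_t`), and the
   background is the shortest `ω/σ²`-ranked prefix whose cumulative weight
   reaches `T`. Two temporal features drive the adaptation inside a fixed
   region of interest (ROI) built from the first 100 frames of detections:
   * the learning rate is scheduled from the global structural similarity
     of consecutive ROI crops, `α = (1 − SSIM)/80`, so a quasi-static
     scene almost freezes the model and dwelling targets are not absorbed;
   * the per-pixel component count is set to the number of merged peaks of
     a rolling 256-bin intensity histogram (peaks closer than 30 gray
     levels collapse into the taller one); outside the ROI it is fixed at 2.
2. **Con-UNet** — a UNet-style encoder–decoder for per-pixel binary
   classification in which every 2×2 max-pooling block is replaced by a
   3×3 stride-2 convolution (the subsampling step learns features instead
   of discarding them), all 3×3 convolutions use reflect padding,
   upsampling is hole-free nearest-neighbour followed by a convolution,
   and the output layer is a sigmoid. The network, its backward pass and
   the Adam training loop are implemented in NumPy.
3. **Fusion** — the motion mask and the network mask are combined
   pixel-wise (bitwise OR by default, so the network fills motion holes)
   and refined morphologically (3×3 ellipse opening, 5×5 ellipse closing).

The package also provides the evaluation stack (precision / accuracy /
IOU / recall with micro-averaging; Brenner, Roberts and SMD2 no-reference
sharpness with relative-difference comparison), a FLOPs counter for the
network family, and a seeded synthetic-scene generator that reproduces the
statistical regime the method targets: small low-contrast targets with
dwell-style intermittent motion, illumination drift, oscillating clutter
and sensor noise, with exact ground-truth masks.

## Worked example

Measure the stay-hole effect and the benefit of each temporal feature on
the packaged dwelling-flock benchmark (four clustered targets, dwell
probability 0.8, 400 frames of 96×128, under 2% foreground):

```python
>>> from midirseg.experiments import ablation_recalls, fused_benchmark
>>> ablation_recalls(seed=1)
{'gmm': 0.1885, 'gmm_lr': 0.2410, 'itf_gmm': 0.4695}
```

The plain mixture model recovers only 19% of target pixels after warm-up —
the flock interiors have been absorbed. SSIM-scheduled learning rates
raise recall to 24%, and histogram-driven component counts to 47%: each
temporal feature strictly helps, and the ordering mirrors the ablation
trend the method was designed around. The full pipeline closes the gap by
fusing in a network trained on 24 synthetic pairs for 120 epochs:

```python
>>> fused_benchmark(seed=1)["fused"]
{'precision': 0.9545, 'accuracy': 0.9991, 'iou': 0.9435, 'recall': 0.9879, ...}
```

i.e. the fused masks recover 98.8% of target pixels at 95.5% precision,
while either input alone is substantially worse (the background model has
IOU 0.46; the numbers above are what these calls print, rounded to 4
digits).

The same experiments are scriptable from the shell:

```sh
midirseg synth --benchmark --seed 1 --out scene/
midirseg bgs --frames scene/frames --mode itf-gmm --out masks/
midirseg eval --pred masks/ --truth scene/masks --skip 100
midirseg flops              # unet: 60.44 GFLOPs, conunet: 62.86 GFLOPs
```

Subcommands: `synth`, `bgs`, `train`, `segment`, `fuse`, `eval`,
`quality`, `flops`, `run` (full configured pipeline with a manifest).

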