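# vesselac

Level-set segmentation of blood vessels in 2-D grayscale medical images
(DSA, MRA, CT, ultrasound), for image-analysis researchers and tool
builders who need vessel masks from modalities where global thresholding
fails. The package combines a **kernel-localized region energy** — robust
to the intensity inhomogeneity that defeats global two-phase models — with
a **multiscale vesselness vector field** that pulls the contour along thin,
low-contrast branches, plus automatic contour initialization,
narrowband/steady-point acceleration, a synthetic vascular phantom
generator with exact ground truth, and contour evaluation metrics.

## The model

The segmentation contour is the zero set of a level-set function φ
(interior {φ < 0}). Around every point x, local interior/exterior
intensity means are formed with a Gaussian window K_σ and a smoothed
Heaviside H_ε:

    f1(x) = ∫ K_σ(x,y) H_ε(−φ(y)) I(y) dy / ∫ K_σ(x,y) H_ε(−φ(y)) dy
    f2(x) = the same with 1 − H_ε(−φ)

and φ evolves by explicit Euler on

    ∂φ/∂t(z) = δ_ε(φ(z)) [ λ₁ ∫K_σ(z,x)(I(z)−f1(x))² dx − λ₂ ∫K_σ(z,x)(I(z)−f2(x))² dx ]
             + v δ_ε(φ(z)) div(∇φ/|∇φ|)                   (length penalty)
             + μ (∇²φ − div(∇φ/|∇φ|))                     (distance regularization)
             + λ f_ε(R(z)) |V(z)·∇φ(z)|                   (vascular vector field)

Each pixel joins whichever region fits its intensity better *locally*, so
slowly varying brightness along a vessel does not break the competition.
The vascular vector field V is the along-vessel Hessian eigenvector, gated
by a Frangi-style multiscale vesselness score

    R = exp(−R_B²/2α²)(1 − exp(−S²/2β²)),  R_B = |λ₁|/|λ₂|,  S = √(λ₁²+λ₂²)

(zero unless λ₂ < 0, i.e. bright vessel on dark background), with a smooth
speed switch f_ε(R) = ½[1 + (2/π) arctan((R−ε)/ε)]. With the default
λ = −0.1 the VVF term extends the contour along vessels into weak branches.

The contour starts automatically from a thresholded vesselness mask,
encoded as the three-valued field φ₀ ∈ {−ρ, 0, +ρ}, and updates are
restricted to a narrowband around the zero set; pixels whose label and
value stop moving are frozen permanently. Defaults follow the published
operating point: Δt = 0.1, v = 0.2, μ = 1.0, λ = −0.1, τ = ε = 0.05,
ρ = 2, σ = round((H+W)/16).

Results are scored with Dice overlap and MRMSE — for matched boundary
point pairs within a (2r+1)×(2r+1) window the mean squared distance, with
a 2r² penalty per unmatched point (r = 12 by default; the printed formula
takes no square root, so units are px²).

## Worked example

```bash
python examples/segment_phantom.py
```

renders the default 110×110 Y-shaped phantom — a bright trunk (intensity
1.0) splitting into two thinner branches (0.8 and 0.6) over a dark
background, with Gaussian noise of standard deviation 0.28 × the intensity
range — and segments it with the default configuration:

```
iterations          : 37 (converged)
Dice vs ground truth: 0.9229
MRMSE (r=12)        : 0.2412  (k1=398 matched, k2=0/k3=0 unmatched)
```

Dice 0.92 at this heavy noise level means the recovered region almost
coincides with the true vessel despite three different branch
intensities; MRMSE ≈ 0.24 px² means the recovered boundary tracks the
true vessel wall at sub-pixel distance, with every truth boundary point
matched. `examples/vesselness_map.py` and `examples/evaluate_masks.py`
walk through the vesselness field and the metrics in the same style.

The same pipeline is available from the shell:

```bash
vesselac phantom --seed 1 --noise 0.28 --out ph/
vesselac segment --image ph/image.tif --out seg/
vesselac evaluate --truth ph/mask.png --pred seg/mask.png
```

`segment` accepts a YAML config (flat keys mirroring `vesselac.RunConfig`)
and writes the mask, sub-pixel contours as CSV, and the per-iteration
energy trace.

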