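# Methods

## Model

The segmenter evolves a level-set function φ on the pixel grid (0-based
(row, col), row increasing downward; interior {φ < 0}). Three forces act:

1. **Localized region force.** Around each point, interior and exterior
   intensities are summarized by Gaussian-kernel-weighted means f1/f2
   (window scale σ), with the interior selected by a smoothed Heaviside
   H_ε(−φ) of width ε_h. The data force at a pixel z compares I(z) against
   the fitting means of all neighbors under the kernel,
   δ_ε(φ_z)[λ₁∫K(z,x)(I(z)−f1(x))²dx − λ₂∫K(z,x)(I(z)−f2(x))²dx], so the
   contour settles where the pixel intensity sits halfway between the
   local interior and exterior means — the local edge. Because the means
   are local, a vessel whose brightness drifts along its length still
   wins the competition everywhere (the failure mode of global two-phase
   models). The regularized delta δ_ε(φ) confines the force to the
   vicinity of the contour.
2. **Geometric terms.** A length penalty v·δ_ε(φ)·div(∇φ/|∇φ|) smooths the
   contour; a distance-regularization term μ(∇²φ − div(∇φ/|∇φ|)) keeps
   |∇φ| ≈ 1 near the contour so the explicit scheme stays stable without
   re-initialization.
3. **Vascular vector field (VVF).** A Frangi-style vesselness score
   R ∈ [0,1] is computed from the σ²-normalized Hessian eigenvalues over a
   scale sweep (bright-vessel polarity: zero unless λ₂ < 0); the
   along-vessel eigenvector v1, gated by R > τ and sign-aligned with ∇φ,
   contributes λ·f_ε(R)·|V·∇φ|. With λ < 0 this extends the contour along
   vessels into thin, weak branches that the region force alone would
   round off.

The evolution is explicit Euler with step Δt on a narrowband around the
zero set. Initialization is automatic: threshold the vesselness map at the
same τ, remove components and fill holes smaller than `min_object_px`, and
encode the mask as the three-valued field {−ρ, 0, +ρ} (boundary pixels on
the mask side are set to 0, so the contour starts within a pixel of the
mask outline).

## Parameters

| name | default | units | meaning / why this value |
|---|---|---|---|
| `sigma` | round((H+W)/16) | px | localization window; ties the local statistics to the image size |
| `eps_h` | 1.0 | px | Heaviside/Dirac width; 1 px is the conventional sub-grid smoothing and keeps δ_ε supported near the contour |
| `lambda1`, `lambda2` | 1.0 | — | interior/exterior residual weights; equal keeps the region competition fair |
| `v` | 0.2 | — | length penalty (published operating point) |
| `mu` | 1.0 | — | distance regularization (published operating point); Δt·μ = 0.1 is within the explicit-diffusion stability bound |
| `dt` | 0.1 | — | explicit Euler step (published operating point) |
| `lam_vvf` | −0.1 | — | VVF weight; negative extends along vessels (published operating point) |
| `alpha` | 0.5 | — | blobness gate of the vesselness score (standard choice) |
| `beta` | adaptive | — | contrast gate = half the maximum structuredness S over the *whole* scale sweep; one shared gate keeps σ²-normalized scales comparable (a per-scale gate re-amplifies structureless large-scale responses into a halo around vessels) |
| `scales` | {1, 1.5, 2, 3} | px | Hessian scale sweep. A scale σ responds to tube diameters ≈ 2√2·σ and its response spreads ≈ σ beyond the boundary; the sweep covers 2–8 px diameters, matching the thin-vessel role of the VVF. For images with thicker vessels, extend via config/CLI. |
| `tau` | 0.05 | — | vesselness gate of the VVF and of the automatic initialization (published value) |
| `eps_v` | 0.05 | — | threshold of the speed switch f_ε (published value; f_ε(0)=0.25, f_ε(τ)=0.5) |
| `rho` | 2.0 | px | three-valued initialization height (published value) |
| `init_threshold` | 0.05 | — | vesselness cut for the rough mask (reuses τ) |
| `min_object_px` | 20 | px | small-component removal / hole filling in the rough mask |
| `band_width` | 4 | px | narrowband half-width (Chebyshev); covers the δ_ε support plus one-step motion |
| `freeze_patience` | 10 | iters | iterations without motion before a pixel is frozen (None disables) |
| `steady_tol` | 1e−4 | φ-units/iter | "did not move": no sign change and \|Δφ\| below this. Purely sign-based stability would freeze never-visited pixels immediately; the tolerance separates advancing fronts (\|Δφ\| ~ 3e−3..3e−2) from equilibrated ones |
| `stop_frac`, `stop_patience` | 1e−3, 20 | — | stop when the fraction of band pixels changing sign stays below `stop_frac` for `stop_patience` iterations |
| `max_iters` | 300 | iters | hard cap; default phantom runs converge in ~40–80 iterations |
| `mrmse_radius` | 12 | px | MRMSE matching-window radius (published evaluation setting) |

## Design choices where the design was open

- **Data-force form.** The flow implemented is the kernel-localized
  binary-fitting gradient flow stated above. Two variants were evaluated
  and rejected: weighting the *neighbor* intensities I(y) against f1/f2 at
  the center makes the force at a pixel independent of its own intensity
  and leaves a systematic sub-pixel boundary offset; additionally
  weighting the kernel integral by δ_ε(φ(x)) scales the force by the
  measure of the curve inside the window (~3–8% at the default σ), slowing
  convergence by an order of magnitude without changing the minimizer.
  The implemented form is the one whose equilibria sit on local edges and
  whose convergence speed matches the intended operating point (tens of
  iterations on the phantom).
- **Interior convention.** The interior indicator is H_ε(−φ), so f1 is
  always the interior mean under the {φ < 0} convention used everywhere.
- **Heaviside branch.** The saturated regularized Heaviside is symmetric:
  0 below −ε, 1 above +ε, arctan ramp between; its derivative is the
  regularized Dirac δ_ε(x) = (1/π)ε/(ε²+x²).
- **Freezing rule.** A pixel is frozen when it has not moved (no sign
  change and |Δφ| < `steady_tol`) for `freeze_patience` consecutive
  iterations *and* |φ| ≥ ρ/2 (pixels on the contour itself stay active).
  Freezing is permanent; the safety check (identical masks with and
  without freezing) is part of the test suite and the acceptance script.
- **MRMSE matching.** Nearest-within-window, many-to-one: each truth
  point matches its nearest evolved point inside the (2r+1)×(2r+1) window;
  k3 counts evolved points never selected and with no truth point in
  their own window. The printed formula is computed with no square root,
  so values are mean squared pixel distances. Both masks' boundaries are
  traced by the same sub-pixel marching-squares extraction.
- **Initialization enhancement.** The rough vessel mask is a threshold of
  the already-computed multiscale vesselness (plus morphological cleanup)
  rather than a separate vessel-enhancing diffusion PDE: it needs only
  rough boundaries, costs nothing extra, and is swappable
  (`--init-mask` accepts any user-supplied mask).

## Numerics

- All kernel-weighted sums use the truncated Gaussian window (radius
  ⌈2σ⌉, renormalized), which is exactly separable; they are evaluated on
  the full grid by two 1-D convolutions with zero padding, which realizes
  the stencil clipped at the image border (numerator and denominator of a
  weighted mean clip identically, so means stay exact). Narrowband
  restriction selects pixels from that full-grid computation, so a banded
  update equals the full update at band pixels exactly.
- Where interior or exterior kernel mass falls below 1e−10 (deep inside /
  outside), f1/f2 fall back to the plain kernel-weighted image mean; the
  two residuals then cancel, keeping the force defined without bias.
- Gradient, curvature and Laplacian use central differences (one-sided at
  borders); the curvature denominator is floored at 1e−8.
- Hessian responses use sampled derivative-of-Gaussian kernels with
  corrected discrete moments (zero DC, unit response to x and x²/2), so a
  flat image scores exactly zero and quadratics are differentiated
  exactly; responses are multiplied by σ² for cross-scale comparability.
- Eigen-decomposition of the symmetric 2×2 Hessian is closed-form;
  eigenvalues are ordered by magnitude, ties in the multiscale maximum
  keep the smallest scale, and the degenerate zero Hessian gets
  v1 = (1,0) by convention (irrelevant in practice: R = 0 there).
- Images are linearly rescaled to [0, 1] at load time (constant images
  map to zeros; RGB by channel mean), making every threshold transferable
  across 8- and 16-bit inputs. Dark-vessel images are handled by
  inversion (`dark_vessels` / `--dark-vessels`).
- Total energy (data + length + regularization) is recorded per iteration
  as a diagnostic; stopping uses the sign-change criterion, not the
  energy.

## The synthetic phantoms, and what the tests do and do not show

The phantom generator rasterizes tube polylines (all pixels within a
half-width of the polyline) with per-branch constant intensities on a dark
background, then adds seeded Gaussian noise with standard deviation
`noise_fraction` × (max branch intensity − background), clipping to [0,1].
The default verification image is a 110×110 Y-shaped vessel with branch
intensities 1.0 / 0.8 / 0.6 (half-widths 3 / 2 / 2) at noise fraction
0.28; truth mask and centerline are exported alongside.

This emulates the key difficulties the model targets — branch-dependent
brightness (intensity inhomogeneity at branch granularity), thin
structures, heavy noise — but not others found in real angiograms:
smooth within-branch intensity drift, background texture and anatomy,
point-spread blur at vessel walls (phantom edges are binary), contrast
falloff with vessel depth, or imaging artifacts. Passing the phantom
tests therefore establishes the correctness and stability of the
machinery and its behavior under noise and piecewise-constant
inhomogeneity; performance figures on real modalities must be measured on
real data.

## Problem sizes

Tests and the acceptance script run on the 110×110 default phantom and
tube images up to 80×120; full runs converge in ~40–80 iterations at
roughly 10 ms per iteration, so the complete suite and the acceptance
script each finish in well under a minute.

## Known limitations

- 2-D only; no volumetric (3-D) extension.
- Bright-vessel polarity is assumed after optional inversion; mixed
  polarity in one image is not handled.
- The VVF extends contours slightly past abrupt vessel *ends* (tube tips),
  where vesselness support spills over — the price of the force that
  carries the contour into weak branches.
- MRMSE is sensitive to isolated spurious components: a single unmatched
  blob adds 2r² per boundary point, so it can jump while Dice moves
  little.
- Explicit Euler with the published step; no CFL adaptation. Very large
  `v` or `mu` would require a smaller `dt`.
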