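"""Segment the default synthetic Y-vessel phantom end to end.

Renders a 110x110 branching vessel (three branch intensities, 28% Gaussian
noise), runs the full pipeline — multiscale vesselness, automatic contour
initialization, level-set evolution — and scores the result against the
phantom's exact ground truth.
"""
import vesselac as va

phantom = va.render_phantom(va.default_y_phantom(seed=1, noise_fraction=0.28))
result = va.run(phantom.image, compute_energy=False)

overlap = va.dice(result.mask, phantom.mask)
boundary = va.mask_mrmse(phantom.mask, result.mask, r=12)

print(f"iterations          : {result.iterations} ({result.stop_reason})")
print(f"Dice vs ground truth: {overlap:.4f}")
print(f"MRMSE (r=12)        : {boundary.value:.4f}  "
      f"(k1={boundary.k1} matched, k2={boundary.k2}/k3={boundary.k3} unmatched)")

# Dice near 1 means the segmented region almost coincides with the true
# vessel; MRMSE is the mean squared boundary distance in px^2 (plus 2 r^2
# for each unmatched boundary point), so values well below 1 mean the
# recovered contour tracks the true vessel wall at sub-pixel accuracy.
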