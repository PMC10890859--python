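# ossim — optically sectioned structured-illumination microscopy, end to end

Widefield fluorescence microscopy collects light from above and below the
focal plane, burying in-focus structure under a haze of background. Optical
sectioning by structured illumination (OS-SIM) rejects that background with
ordinary widefield optics: the sample is excited with a sinusoidal stripe
pattern whose modulation depth is high only at focus, three images
I₁, I₂, I₃ are acquired with the pattern stepped by 0, 2π/3, 4π/3, and the
in-focus content is demodulated from the stripe contrast. The classical
squared-difference (SD) reconstruction

    I_R = sqrt((I₁−I₂)² + (I₂−I₃)² + (I₁−I₃)²)

is exact for ideal phase stepping but amplifies noise and breaks down when
the sample moves between exposures.

`ossim` is a self-contained laboratory for studying and improving OS-SIM
reconstruction **in silico**, aimed at microscopists and image-analysis
researchers. It provides:

* **Physics simulation** — scalar Born–Wolf 3D point spread functions, OTFs,
  stripe patterns, a two-plane and a full volumetric image-formation model,
  and a Poisson + Gaussian detection-noise model whose signal level is set by
  a Poisson factor η (peak expected photon count = η × 10⁶).
* **Phantoms** — 3D filament meshes, procedural 2D textures, and moving-object
  frame triplets; every generator is a pure function of (parameters, seed).
* **Classical reconstruction** — widefield estimate, SD, phase-corrected SD
  (pixelwise least-squares demodulation for arbitrary known phases, with
  carrier/phase estimation from the raw frames), and HiLo-style filtered SD
  (α·HP(widefield) + (1−α)·LP(corrected SD) plus a stripe-suppression notch).
* **Learned reconstruction** — a residual channel attention network (RCAN)
  and a windowed-attention video transformer (VSR) that map the three raw
  frames to one sectioned frame, built on a small numpy reverse-mode
  autodiff engine inside the package, with a randomized simulation-based
  training-set generator and a two-stage (MSE → L1) Adam training schedule.
* **Evaluation** — SSIM scoring against noise-free sectioned ground truth,
  SSIM-versus-η noise sweeps on filament volumes, a moving-sample benchmark,
  and missing-cone OTF analysis.

## Worked example

Simulate a noisy two-plane scene (in-focus texture over a defocused
background, NA 1.2 water immersion, 600 nm emission, 86 nm pixels, peak
photon count 100), estimate the pattern from the data, and reconstruct:

```python
import numpy as np
from ossim import (NoiseModel, widefield_estimate, sd_reconstruction,
                   corrected_sd, hilo_filtered)
from ossim.recon import estimate_pattern_parameters
from ossim.scenarios import two_plane_scene, reference_optics
from ossim.evaluate import ssim_score
from ossim.optics import compute_psf
from ossim.forward import default_psf_shape
from scipy.signal import fftconvolve

stack, in_focus, background = two_plane_scene(
    seed=42, noise=NoiseModel(poisson_factor=1e-4))
est = estimate_pattern_parameters(stack)
print(f"pattern estimate: {est.spatial_frequency:.3f} cycles/um "
      f"at {est.orientation:.3f} rad")

cfg = reference_optics()
psf = compute_psf(cfg, default_psf_shape(cfg))
gt = fftconvolve(in_focus, psf.plane(0.0), mode="same")
for name, img in [("widefield", widefield_estimate(stack)),
                  ("SD", sd_reconstruction(stack)),
                  ("corrected SD", corrected_sd(stack, est)),
                  ("filtered SD", hilo_filtered(stack, phases=est))]:
    print(f"SSIM vs sectioned ground truth, {name:13s}: {ssim_score(img, gt):.3f}")
```

Output:

```
pattern estimate: 2.455 cycles/um at 3.140 rad
SSIM vs sectioned ground truth, widefield    : 0.451
SSIM vs sectioned ground truth, SD           : 0.126
SSIM vs sectioned ground truth, corrected SD : 0.126
SSIM vs sectioned ground truth, filtered SD  : 0.664
```

The stripe frequency is recovered to 0.2% of the true 2.459 cycles/µm. At a
100-photon peak the raw SD reconstruction is *worse* than the widefield
image — demodulation amplifies shot noise — while the filtered SD, which
takes its noisy low frequencies from the sectioned image and its fine detail
from the widefield image, scores best. This noise sensitivity of subtractive
reconstruction is the package's central benchmark, and the learned
reconstructions (`ossim.nn`) are trained on exactly these simulations to
beat it.

A command-line surface wraps the same pipeline:

```bash
ossim simulate volume --seed 1 --out raw.tif
ossim reconstruct raw.tif recon.tif --method hilo --layout z,phase
ossim train --network rcan --n-static 150 --epochs 14 --out rcan.npz
ossim evaluate sweep --replicates 3 --out sweep.csv --plot sweep.png
```

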