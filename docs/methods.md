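# Methods

This note records the models implemented in `ossim`, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the simulation-based tests do and do not demonstrate about real data.

## Image formation

**Point spread function.** The widefield intensity PSF is the scalar
Born–Wolf defocus integral

    h(r, z) = | ∫₀¹ J₀(k NA r ρ) · exp(−i k z ρ² NA² / 2n) · ρ dρ |²,

k = 2π/λ_em, evaluated by 128-node Gauss–Legendre quadrature over the
aperture coordinate ρ on the unique lateral radii of the voxel grid. No
vectorial, polarization or index-mismatch terms are included. The volume is
normalised to unit sum; the focal plane sits at the central voxel (odd y/x
counts are required; even z is allowed with focus at ⌊z/2⌋). Defaults follow
the reference simulation conditions: NA 1.2 water immersion (n = 1.33),
λ_em = 600 nm, λ_ex = 488 nm, 86 nm isotropic voxels. At these settings the
computed lateral FWHM is ≈ 260 nm against the λ/2NA estimate of 250 nm.

**Stripe pattern.** P_n(x) = ½(1 + m cos(2πν(x·cosθ + y·sinθ) + φ_n)),
with default phases 0, 2π/3, 4π/3. Normalising the pattern to mean ½ makes
the uniform-average-illumination identity exact: the mean of the three phase
images equals half the uniformly illuminated image, to machine precision.
The default stripe frequency is ν = NA/λ_ex (half the detection cutoff),
2.459 cycles/µm at the reference optics. Pattern modulation decays axially
as m(z) = m₀ exp(−(z/z_m)²) with z_m = n·λ_ex/NA² (≈ 450 nm here); this
single Gaussian envelope stands in for the full excitation-OTF falloff and
is the mechanism that makes sectioning possible at all.

**Two-plane scenes.** A single-plane acquisition is modelled as an in-focus
structure and a defocused background: frame_n = blur(in·P_n, psf₀) +
w·blur(bg·P'_n, psf_z), where psf_z is the PSF slice at the background's
defocus (default 1.5 µm) and P'_n carries the axially attenuated modulation
m(z_defocus) ≈ 0 — out-of-focus structure sees essentially uniform light.
Convolutions are linear (zero-padded FFT convolution), so a delta kernel is
an exact identity.

**Volumetric scans.** For a focal position z₀ the detected plane is the 3D
convolution of the pattern-excited phantom with the PSF, sampled at z₀, with
the pattern (and its modulation envelope) refocused to z₀. Splitting the
pattern into its mean and carrier parts reduces the whole scan to four 3D
FFT convolutions (one widefield term plus one modulated term per phase),
independent of the number of focal planes.

**Noise.** The noise-free stack is scaled so its maximum equals 10⁻⁶; each
pixel is replaced by a Poisson draw with mean value·η·10¹², then zero-mean
Gaussian read noise (σ in photon counts) is added and the result clipped at
zero. Peak expected photon counts are therefore η·10⁶: 100 photons at
η = 10⁻⁴, 20 at 2×10⁻⁵, 5 at 5×10⁻⁶ — the low-photon regime the benchmarks
probe. σ defaults to 1 count and is deliberately independent of η, so the η
sweep varies shot noise against a fixed read-noise floor. Per-pixel mean and
variance of this model are validated by Monte-Carlo tests (variance ≈ λ + σ²).

## Classical reconstruction

**Widefield estimate**: the per-pixel mean of the three frames.

**SD**: the root of summed pairwise squared differences. On an ideal uniform
plane, frame_n = B(1 + m cos(θ + φ_n)), the three squared differences sum to
4.5·(Bm)² independently of θ, so the output is the constant √4.5·B·m — an
identity the tests assert symbolically and numerically.

**Corrected SD.** For arbitrary known phases the stripe amplitude is
recovered by the pixelwise least-squares solve of the three-equation linear
system I_n = B + p·cosφ_n − q·sinφ_n (the inverse-matrix demodulation),
implemented in closed pairwise form: with X₁ⱼ = (I₁−Iⱼ)/(2 sin((φ₁−φⱼ)/2))
and Δ = (φ₂−φ₃)/2,

    A² = (X₁₂² + X₁₃² − 2·X₁₂·X₁₃·cos Δ) / sin² Δ,

returning A = B·m. This reduces to SD/√4.5 at ideal phases, is invariant
under frame relabelling, and is validated against a brute-force per-pixel
least-squares fit. It is singular when two phases (nearly) coincide; that
degeneracy raises an error naming the offending pair (tolerance 10⁻³ on
|sin(Δφ/2)|).

**Pattern estimation.** The carrier is located in the difference frames
(frame minus three-frame mean), whose spectra contain only the modulated
terms — subtracting the widefield component cancels the static structure
spectrum exactly, so the mean difference power spectrum peaks at ±k₀
regardless of scene content. The peak is refined to sub-bin precision by
deterministic Nelder–Mead maximisation of the Hann-windowed DFT power
(frequency accuracy ≈ 0.2% on textured scenes). Per-frame phases come from
the complex coefficients of the original frames at the refined carrier; the
residual structure bias common to all frames is removed by an alternating
estimate of the common component. Peak detection uses an extreme-value
threshold: white-noise power-spectrum bins are approximately exponential,
so a genuine carrier must exceed ~2·(ln N + 1)/ln 2 times the median bin.
Below that, the estimate is flagged low-confidence and, when the stack
carries its simulation pattern, falls back to those configured parameters
(in simulation the nominal pattern is the true one).

**Filtered SD (HiLo-style).** α·HP(widefield) + (1−α)·LP(corrected SD),
with HP = 1 − LP complementary Gaussian frequency filters at a cutoff of
half the pattern frequency, followed by a Gaussian annular notch of width
10% of ν centred on the carrier ring. The sectioned image is rescaled to
the widefield mean before mixing so the two bands join at one intensity
scale. α defaults to the estimated modulation depth clipped to [0.1, 0.9].

## Learned reconstruction

Because the networks must train and run on a single CPU, they are built on
a small reverse-mode autodiff engine (`ossim.nn.autodiff`) written on numpy:
broadcasting arithmetic, batched matmul, stride-1 2D convolution via
sliding-window einsum, softmax, layer norm, GELU and the other elementwise
ops, all gradient-checked against central differences to ~10⁻⁷.

**RCAN** (fast reconstruction): a 7×7 learnable head, groups of residual
channel attention blocks (two 3×3 convolutions plus a channel gate computed
by global pooling and two 1×1 convolutions, with a residual connection),
a body convolution with a long skip, and a 3×3 reconstruction tail mapping
3 input frames to 1 output frame. The reference configuration (3 groups ×
10 blocks × 96 filters, attention reduction 16) has 5,367,253 parameters,
asserted against an independent closed-form count. The desk-scale default
(1 group × 2 blocks × 8 filters) trains in about half a minute.

**VSR** (high-fidelity reconstruction): the three frames are embedded by a
3×3 convolution and passed through windowed channel attention blocks, each a
pair of Swin-style transformer layers — windowed multi-head self-attention
with the window partition cyclically shifted on alternate layers, then an
MLP, both with layer norm and residuals — followed by one residual channel
attention block; a final convolution fuses one output frame. The learnable
per-head additive bias plays the role of the relative-position table, and
no attention mask is applied after the cyclic shift (at these window counts
the wrap-around coupling is a negligible, documented simplification). Depth
hyperparameters unspecified by the architecture's description (layers per
block, heads, width) default to 2/4/48 and are fully configurable; the
desk-scale variant uses 2 blocks, 2 heads, width 16, window 8.

**Training data.** Every example draws its optics (NA 1.0–1.3), pattern
(frequency 1.6–2.9 cycles/µm, orientation 0–2π, modulation 0.6–1.0),
background defocus (1–3 µm), background weight (0.2–1.0) and noise level
(log-uniform η, 5×10⁻⁶–10⁻³) independently, so networks generalise across
imaging conditions rather than memorising one microscope. Static scenes use
procedural textures (multiscale noise, blob fields, 2D filaments); moving
scenes use rigidly translating Gaussian-blob objects with sub-pixel Fourier
shifts, seen at three successive positions by the three phase frames. The
training target is the in-focus plane convolved with the in-focus PSF — the
diffraction-limited sectioned image; the goal is background and noise
removal, not lateral super-resolution. For moving scenes the target is the
second (middle) frame, the timepoint the reconstruction should represent.
Inputs and targets are percentile-normalised (1st/99th) per example; the
convention is recorded in every checkpoint.

**Schedule.** Adam (default learning rate 10⁻³ for the tiny configurations,
batch 8), MSE loss for the first half of the epochs and L1 for the second
half. Training is bit-deterministic from the config seed; a non-finite loss
aborts and restores the last epoch's weights.

**Inference.** Frames are percentile-normalised and processed in overlapping
tiles blended with linear ramps; a margin of a quarter overlap at interior
tile edges is discarded because the network's padding boundary contaminates
it. Tiling is exact for single-tile frames and for attention-free networks;
with channel attention it is approximate (the gate pools global statistics,
measured seam error ~2% RMS at forced tiling), which the tests document.

## Evaluation protocol

**SSIM** is computed after percentile normalisation of both images, with a
Gaussian window (σ = 1.5) and the data range taken from the normalised
ground truth. Two constant images score ≈ 1 under this luminance
normalisation — an edge case irrelevant for structured scenes.

**Noise sweep.** Per replicate, a filament-mesh volume (20 random-walk
filaments, thickness 2 voxels — free parameters of the benchmark, recorded
in its config) is scanned noise-free once; for each η on a descending log
grid (4 points per decade, 10⁻⁶–10⁻³) noise is applied, the pattern is
estimated once per acquisition from the plane with the strongest modulation,
every method reconstructs plane by plane, and the 50-slice maximum-intensity
projection is scored against the noise-free sectioned ground-truth MIP. The
"sharp drop" of a method is the η at the top of the adjacent-grid interval
with the largest mean-SSIM decrease. Volumes default to 64×96×96 voxels so
three replicates run in seconds; all seeds are recorded in the output table
for bit-exact reruns.

**Motion benchmark.** Eight scenes of translating objects (speed ≤ 2 px per
frame) over a defocused background, with noise at η = 10⁻⁴ — high enough
signal that motion artefacts rather than shot noise dominate the comparison,
which is the quantity this benchmark isolates. Scores are SSIM against the
second frame's sectioned image; stripe-artefact energy is integrated in
small spectral discs at ±k₀ of the carrier (the artefact is coherent with
the illumination and directional, so an oriented measure separates it from
broadband noise residue).

**Missing cone.** Point-source volumes are scanned, reconstructed plane by
plane, and the DC-normalised spectral energy in a one-pixel-radius tube
around the kz axis (|kz| > 0) is compared between the sectioned
reconstruction and the widefield volume. Widefield transfers essentially no
purely axial content (measured < 10⁻⁷ of the in-plane energy), so the
ratio — about 3–5 under the default conditions, against a package-constant
acceptance threshold of 2 — quantifies the axial information the
reconstruction restores.

## Known limitations

* The simulations omit camera fixed-pattern noise, pattern drift, chromatic
  effects and aberrations; passing benchmarks here demonstrates algorithmic
  behaviour under the stated image-formation model, not performance on any
  particular instrument.
* Under this package's photon normalisation the SSIM-versus-η curves decline
  steadily rather than cliff-like, so the sharp-drop locator lands at the
  dim end of the grid for all methods, and the filtered SD loses to plain SD
  at the brightest signal levels (where the low-pass discards detail that
  noise-free SD keeps) and at the dimmest (where the fallback modulation
  estimate drives α to 0.9). These are properties of the documented defaults
  and are reported as measured.
* The desk-scale network configurations demonstrate orderings (learned >
  subtractive at low signal; transformer suppresses motion stripes), not the
  absolute reconstruction quality that full-scale training would reach.
* Procedural textures approximate the diversity, not the statistics, of
  natural-image training corpora.
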