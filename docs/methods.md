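# Methods

## Imaging model

The instrument modeled here is an epi-illumination UVC microscope: a
275 nm LED, spatially homogenized by a large-core multimode fiber, is
relayed through a rotatable half-ring amplitude mask in a pupil plane
onto the sample; the reflected light is collected by an all-mirror
Cassegrain-type objective (NA 0.65) whose secondary mirror obscures the
pupil center up to an equivalent NA of 0.27. The coherent transfer
function is therefore a binary annulus between `na_obs/λ` and `na/λ`
(both edges closed on the discrete grid; pixels on the half-plane
dividing line belong to both half-rings). The half-ring mask yields
partially coherent oblique illumination whose asymmetry encodes the
sample's phase; four mask rotations (0°, 90°, 180°, 270°) provide the
orientation diversity needed to retrieve phase and absorption jointly.

The sample is treated as a thin slab crossed twice (reflection doubles
the optical path): per pixel, phase φ = 2·(2π/λ)·δn·t and attenuation
exponent μ = 2·(2π/λ)·k·t, where δn is the real refractive-index
increment over the medium, k the extinction coefficient (imaginary part
of the refractive index) and t the local thickness. For weak objects
(μ, |φ| ≪ 1; the code warns above 0.5) the image spectrum is linear in
(φ̂, μ̂):

    Î(u) = B·δ(u) + h_abs(u)·μ̂(u) + h_ph(u)·φ̂(u)

with B = Σ S|P|² and the standard partially coherent weak-object kernels
built from the source-pupil cross-correlations C₁, C₂ (see the
`optics.compute_wotf` docstring). The sign convention is fixed so a pure
weak absorber lowers intensity: h_abs(0) = −2B. For real S and P, h_abs
is real and even, h_ph purely imaginary and odd; in particular h_ph(0) = 0,
so the mean of the phase map is structurally unrecoverable (the retrieval
pins it through the regularizer; all φ outputs are defined up to a
constant). Correlations are evaluated as zero-padded (linear) FFT
correlations — no wrap-around.

A brute-force reference implementation (`forward.forward_abbe`) performs
the full Abbe source-point sum over the complex transmittance
T = exp(iφ − μ) without linearization. It is normalized to the same
background level and serves as the oracle for the linearized model: for
weak objects the two agree to better than 2 % of the contrast signal,
with the discrepancy shrinking linearly in object strength (it is a
second-order effect). The Abbe sum subsamples the source onto ~64 grid
points by default; `select_source_points` exposes the same discretization
so model comparisons can be made like for like.

## Retrieval

Flat-field corrected difference images d_j = (I_j − B_j)/B_j give, per
spatial frequency, an overdetermined 2-unknown linear system. It is
solved in closed form from the normal equations with Tikhonov weights
τ_abs, τ_ph added to the diagonal. τ trades patterned deconvolution
artifacts (too small) against resolution loss (too large); at the default
256² grid and 50 nm pixels, values of 100–1000 are a useful range and 300
is the default. Note the absolute τ scale is tied to the transfer-
function normalization (grid sums over the pupil), so it shifts with grid
size and pupil sampling; the monotone smoothing behaviour does not.
Frequencies outside the incoherent support |u| > 2NA/λ are zeroed before
the inverse transform. The regularized normal matrix is always
invertible; with τ = 0 the solve raises, since the transfer functions
always lack support somewhere.

The retrieved μ is converted to extinction by k = μλ/(4πL). L is the
effective axial path *per direction* (the double pass is already inside
μ's factor 2). Its default is the depth of field Δz = 1.355 µm of the
obscured pupil (truncated Ewald sphere), which is the slab the instrument
integrates over; structures thinner than Δz therefore come out
underestimated by t/Δz. On synthetic data the generator records the
membrane thickness, and the tests pass it as L so recovered k sits on the
true scale; on real data the thickness is unknown and the default
applies.

## Synthetic data

`make_lsec_phantom` renders an elliptical cell with a thicker nucleus,
a thin peripheral membrane (thickness drawn once per phantom from
100–200 nm) and `n_clusters` sieve plates on the membrane. Default
extinction coefficients: nucleus 8×10⁻⁴, membrane 2.7×10⁻⁴, cluster mean
3.4×10⁻⁴. Each sieve plate is a disc carrying zero-extinction holes
(fenestrations, radii drawn from 50–300 nm — mostly sub-diffraction at
the 212 nm resolution) surrounded by elevated-extinction rims, reflecting
the higher cytoskeletal protein density around the pores; the disc's k
values are rescaled so their mean equals the requested cluster mean.
Sub-pixel pores are recorded in the truth and rendered as single pixels.
δn defaults to 0.02 over the medium for all cellular pixels — real-index
values for LSECs are not established, and this value keeps the phantom
safely inside the weak-object regime. The nucleus thickness defaults to
300 nm: real nuclei are micrometers thick, but that would push φ beyond
the linearized model's validity and break the single-slab assumption of
the μ→k conversion, so the phantom compresses the nucleus while keeping
its extinction contrast. All randomness flows from one integer seed
through one `numpy.random.Generator`; phantoms are bit-reproducible.

What the generator does *not* emulate: 3-D structure and defocus,
organelle texture, autofluorescence, camera fixed-pattern noise beyond
flat fields, thin-film interference in the sieve plates (the coherent
Abbe oracle reproduces such effects qualitatively for thin structures,
but no explicit film model is included), and live-cell dynamics. Passing
tests therefore demonstrate the correctness of the computational chain
under its stated model, not performance on real tissue.

`make_bar_target` renders vertical absorption bars with 16× column
supersampling (periods down to 2 px keep the correct spectral peak);
`make_bead_field` renders sparse 150 nm-radius scatterers with both phase
and extinction contrast, the calibration sample for direction estimation.

## Calibration

*Illumination direction.* A half-ring source makes the transfer function
anisotropic, and an image of small scatterers inherits that anisotropy in
its spectrum. The estimator crops the image with a Gaussian-edged
circular mask (σ = 20 px), takes the periodic component of Moisan's
periodic-smooth decomposition (both steps suppress edge artifacts that
otherwise bury the anisotropy — the naive estimator without them is
measurably worse and a regression test keeps it that way), masks the
log-magnitude spectrum to the nominal support (2NA/λ, 10 px Gaussian
edge), Radon-transforms it at 1° steps and median-filters (3 px) the
center projections. The projection peaks when the integration line runs
along the spectral lobe, i.e. along the illumination axis. The argmax
locates the lobe to the angle step; the phase of the second circular
harmonic of the 180°-periodic profile refines it using the whole lobe,
falling back to the raw argmax if the two disagree by more than 30°
(multi-lobed profile). Two numerical details matter: the half-plane
source mask uses a small tolerance so that dividing-line pixels are kept
on both sides (raw cos/sin rounding otherwise biases the source's mean
direction by several degrees at 45°/90°/135°), and the confidence is
reported as peak/median of the profile with a warning below 1.05.

The remaining 180° ambiguity cannot be resolved in the linear weak-object
regime for phase-dominated scatterers — mirroring the half-ring merely
negates the phase contrast, producing an equally good matched-filter
score up to a shift. The resolver therefore renders a single-bead
template with the *nonlinear* Abbe model under both candidate directions
and keeps the one whose template correlates better with the flat-field
image; the second-order terms break the symmetry cleanly (score margins
around 0.99 vs 0.87 on the synthetic sweep).

*Pupil estimation.* With an off-center pinhole replacing the half-ring,
the image spectrum contains two copies of the pupil decentered to ±u_p.
Each log spectrum is cross-correlated with a zero-mean annulus template
(a matched filter; locally normalized correlation is unstable against the
speckle filling the pupil interior), the strongest peak and its
point-symmetric partner are taken as the copy centers, the copies are
re-centered, averaged over copies and images, and binarized at half the
99th percentile. Near-coincident copy centers (center pinhole) are
reported as degenerate. Three pinhole positions recover the true annulus
with Jaccard ≈ 0.99 on synthetic data; a single image is substantially
worse because the partner copy overlaps the extracted one.

## Fenestration analysis

The analysis runs on the reconstructed k map: (1) three-class
segmentation background/membrane/nucleus by a 3-level Otsu split of the
smoothed map, with small high-extinction islands (sieve plates) returned
to the membrane class and only large components kept as nucleus;
(2) grayscale opening with a paraboloid structuring element (radius
10 px; depth reaching the image dynamic range at that radius) removes the
slowly varying membrane baseline — the opening guarantees background ≤
image, residual ≥ 0, and is idempotent at fixed paraboloid; (3) local
maxima of the residual, restricted to the membrane, are detected by exact
topographic prominence (union-find over descending pixel order —
0-dimensional persistence; the highest peak is measured against the map
minimum), thresholded at 1.5×10⁻⁴ in extinction units; (4) per-cluster
extinction is read from the unsubtracted k map at the peak pixel
(averaging disc radius 1 px), reported against the per-pixel extinction
of the segmented membrane.

Two guards reflect properties of band-limited reconstructions rather
than of real stained masks: detection skips a 6 px margin along the
nucleus and background borders, where Gibbs overshoot of the large
extinction steps would otherwise register as spurious peaks; and maxima
closer than 16 px (800 nm, about one sieve-plate diameter) are merged
into the strongest one, since a plate whose fenestration rims are
partially resolved yields several prominent maxima. With these defaults
the planted-cluster count on a 512² phantom with 100 plates is recovered
within a few percent, and the cluster-above-membrane extinction ordering
is reproduced.

## Instrument formulas and conventions

- Resolution Δx = λ/(2NA) = 211.5 nm at the default parameters
  (rounding to 212 nm); a bar target with `lp_per_mm` line pairs/mm
  bounds the resolving power by 10⁶/lp_per_mm nm (303 nm at 3300 lp/mm).
- Depth of field from the truncated Ewald sphere:
  Δz = (λ₀/n)/(√(1−NA_obs²/n²) − √(1−NA²/n²)) = 1.355 µm. Strictly
  decreasing in NA, increasing in NA_obs.
- Coherence length L_c = λ²/Δλ. The nominal 10 nm bandwidth gives
  7.56 µm; a printed figure of 6.8 µm for this LED corresponds to an
  effective Δλ ≈ 11.1 nm — both evaluations are tested, the discrepancy
  is documented rather than hidden.
- Power budget: LED power × beam-splitter × half-mask × (NA_obs²/NA²) ×
  fiber-core area / LED emitting area ≈ 0.205 mW at the stated parts.
- Conventions: images row-major, origin top-left; angles counter-
  clockwise from +x with physical y up (row index down); lengths nm at
  the sample plane; 32-bit float TIFF with JSON sidecars; simulated
  intensities anchored to background 1.

## Problem sizes

The test suite runs phantoms at 256² (50 nm pixels) and the planted-count
check at 512²; the Abbe oracle uses 64 source points on 64²–256² grids.
These sizes keep every guarantee measurable with comfortable margins
while the whole suite completes in well under a minute of compute per
heavy test.

## Known limitations

- Single-scattering, thin-slab, weak-object model: no 3-D sectioning, no
  multiple scattering, no defocus stacks; accuracy degrades smoothly as
  objects strengthen (tested), but thick samples are out of model.
- Scalar diffraction only; no polarization or aberrations beyond the
  binary annulus.
- Extinction values depend linearly on the assumed path length L; absent
  thickness knowledge they are lower bounds.
- The τ scale is tied to the discrete transfer-function normalization;
  porting settings across grid sizes requires rescaling.
- The direction estimator assumes phase-contrast-bearing point features;
  for purely absorbing samples the 180° disambiguation is undefined in
  principle (the axis estimate still works).
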