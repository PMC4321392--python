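# Methods

## Image standardization

Micrographs acquired at different objectives and digital resolutions are
resampled to 800 × 600 px at a fixed physical scale of 1.6 px/µm, then
cropped to the centered 600 × 600 px window (columns [100, 700) of the
800-wide intermediate, 0-based half-open; rows unchanged). Bilinear
interpolation is the default (nearest-neighbour available); input already on
the canonical 600 × 600 grid passes through unchanged, which makes
standardization idempotent for every image and guarantees that an
already-standard field is analysed exactly as given. Intensities are carried
as float64 after load regardless of file bit depth. Min–max normalization
maps each raster to [0, 1]; a constant raster maps to zeros with a warning
so absolute thresholds downstream behave deterministically rather than
propagating NaN.

## Normalized clustering factor

The 2-D PSD is the squared modulus of the centered DFT. The DC bin is
recorded separately and excluded from all downstream sampling: the mean
intensity offset carries no information about arrangement and would
otherwise dominate clump spectra. Parseval's identity
(Σ PSD / N² = Σ I²) is asserted in tests to 1e-8 relative.

Radial sampling bins every non-DC Fourier pixel by rounded integer radius
k = round(r) (half away from zero), k = 1…300; corner frequencies beyond the
Nyquist ring (k > 300) are discarded, so f_min = 1/600 px⁻¹ and
f_max = 0.5 px⁻¹. Annulus pixel counts n_k are retained alongside the
annulus means PSD_k.

The clustering factor weights each annulus by its **total** power
w_k = n_k·PSD_k — equivalent to averaging over every non-DC sample of the
2-D PSD — and averages ln f:

    f̄ = Σ w_k ln f_k / Σ w_k
    NCF = (ln f_max − f̄) / (ln f_max − ln f_min), clamped to [0, 1]

The log transform is applied to the *frequency* axis. This construction is
pinned by three anchor behaviours: a flat (white-noise) spectrum scores
near 0, a spectrum concentrated at f_min scores near 1, and a power-law
spectrum PSD ∝ f⁻² scores 0.5 in the continuum limit (with w ∝ 1/f the
weighted mean of ln f is the interval midpoint exactly). Log-transforming
power instead of frequency breaks both the midpoint anchor and invariance
to intensity scaling, so that reading was rejected. Total-power weighting
makes NCF exactly invariant under I → c·I (weights scale by c², cancelling),
and radial binning makes it invariant under 90° rotation and flips; both are
asserted to 1e-10.

Two finite-grid facts are worth stating rather than hiding. First, the
white-noise anchor is not exactly 0 on a 600-px grid: with flat power and
n_k ∝ k the weighted mean sits 1/(2 ln 300) ≈ 0.088 above the f_max
endpoint, and the value approaches 0 only as the frequency range grows.
Second, the power-law midpoint anchor is exact only in the continuum: the
discrete sum over k = 1…300 with weights ∝ 1/k overweights the first few
annuli (Σ1/k exceeds ∫dk/k by roughly the Euler–Mascheroni constant,
concentrated at small k) and evaluates to 0.5478, a +0.048 deviation from
0.5. Both values are frozen in the test suite from independent plain-Python
summation oracles.

Per-channel analysis min–max normalizes each channel before the PSD. The
statistic is scale-invariant anyway; normalization keeps stored PSD
magnitudes comparable across channels and images.

## Nucleus detection

The DAPI channel is normalized to [0, 1] and band-passed by the difference
of two normalized disk mean filters of 12 and 18 px diameter (the nucleus
diameter range at the canonical scale), with symmetric boundary padding.
Mean (not sum) filters are essential: a sum filter would rescale with disk
area and destroy the meaning of the 0.005 threshold on [0, 1] input.

Candidate pixels exceed 0.005 in the band-passed image. A Prewitt gradient
magnitude is computed on the same band-passed image using unit-gain kernels
([-1,0,1] ⊗ [1,1,1]/3, Euclidean combination of the two axes), so gradient
values live on the same intensity scale as the 0.005 threshold; the
component-level rule keeps an 8-connected candidate component iff it
contains at least one pixel with gradient > 0.02. The AND of the two
thresholds is deliberately applied at component level: gradient support
lives on blob rims, and a per-pixel AND would hollow out interiors and
return annuli. One record is produced per surviving component with the
unweighted sub-pixel centroid. The unit-gain gradient convention also
suppresses band-pass side-lobe fragments that otherwise appear 16–20 px
outside strong nuclei under pixel noise; with it, detection on the
synthetic suite is exact at zero noise and holds precision/recall ≥ 0.99 at
additive noise σ = 0.05.

No declumping or watershed is applied: touching nuclei merge into one
component and are counted once. This is a documented limitation, tested
explicitly.

Classification compares the green (β-III-tubulin) and red (GFAP) channels at
the pixel nearest each centroid: strict green dominance → neuron, strict red
dominance → glia, exact tie → unclassified.

## Area, density and ratio

A pixel joins the astrocyte mask when its red intensity exceeds 10% of the
red channel's maximum and exceeds the green intensity there; the neuron mask
mirrors the rule. The 10% floor is read per-channel (each rule
self-contained), and the strict dominance inequalities make the two masks
disjoint by construction and invariant to joint rescaling of both channels.
Mean per-cell area divides the class mask total by the class nucleus count
and converts with exactly (1.6 px/µm)² = 2.56 px²/µm². Densities divide
class counts by the standardized field area (600 × 600 px = 0.140625 mm²);
absolute units are this package's convention since only relative changes
are comparable across studies. Zero-count classes yield explicit `None`
values for mean area and the neuron/glia ratio rather than sentinel numbers
or division errors.

## Soma connectivity

A non-excluded soma is *connected* iff it appears in an annotated dendrite
link or its boundary-to-boundary distance (centroid distance minus both
radii) to another non-excluded soma is below 10 px — the separation under
which adjacent somas share a phase-contrast halo. Distance is
boundary-referenced so soma size does not masquerade as proximity, and
connectivity is pairwise (no transitive component analysis is implied by
the metric). The field metric is n_total / n_isolated, ≥ 1 when defined and
flagged undefined for a fully connected field. Somas whose centroid pixel
reaches 95% of the image maximum are assumed dead and excluded (≥ so that a
floor of 1.0 excludes exactly-saturated pixels); links touching excluded
somas are ignored with a warning.

Group comparison reports, per time point, group mean ratios, the percent
change 100·(control − treated)/control, and a two-sided pooled-variance
Student's t-test (Welch available via flag); design cells with fewer than
two replicates omit the p-value with an explicit flag.

## Synthetic scenes: what they emulate and what they do not

Calibration fields: i.i.d. uniform noise; a Gaussian clump exp(−d²/2σ²);
and a random-phase spectral-synthesis field whose expected PSD falls as
f^−β (white Gaussian noise filtered by f^−β/2 in Fourier space, DC zeroed).
Spectral synthesis was chosen over midpoint-displacement fractals because
the PSD is exactly the object the clustering factor consumes.

Cell scenes render nuclei as hard disks of uniform-random diameter in
[12, 18] px at intensity 1 — hard disks, not Gaussian spots, so the
band-pass detector's design assumptions hold exactly at zero noise. Body
footprints are disks sized from mean areas of 1300 px² (neurons, ≈508 µm²)
and 3800 px² (glia, ≈1484 µm²), chosen to match the magnitude of measured
cortical-culture cell areas (roughly 500–650 µm² for neurons and
1450–1750 µm² for astrocytes). Inside a footprint the class's own channel is
0.9 and the other 0.3; where footprints of different cells overlap, each
pixel is owned by its nearest centroid, so strict dominance at every nucleus
centroid always reflects the true class. Ground-truth per-class areas are
the ownership areas before noise. Additive Gaussian noise (default σ = 0,
clipped at zero like a sensor floor) is a free parameter.

Arrangements: *poisson* places centroids uniformly with a default minimum
separation of 19 px (no nucleus-disk overlap, matching the detector's
non-overlap assumption); *thomas* places them as an exact-count
Neyman–Scott process — uniform parents, each point assigned a uniform
parent and scattered with isotropic Gaussian σ — with no separation floor,
since aggregated somata naturally touch. The parent count defaults to
n/8 (cluster occupancies of a few to a few tens of cells, the range
observed for depolarization-induced assemblies); the scatter σ defaults to
15 px. Infeasible packings (dart-throwing exhaustion or an area bound)
raise rather than silently overlapping.

For the aggregation-monotonicity check (mean NCF falling as cluster σ grows
through 5, 15, 40 px) the *nuclei* channel is the readout: nuclei are
compact markers of the point pattern itself, whereas the body channels
convolve the pattern with footprints whose diameter (≈40–70 px) rivals the
cluster scale and confounds the trend.

Soma scenes place connected pairs — two thirds by a boundary gap drawn in
[2, 9] px, one third by a dendrite link between distant somas — on a
jittered anchor grid whose spacing guarantees every non-pair boundary gap
exceeds the requested minimum separation (default 20 px), so the ground
truth isolated set is exactly the unpaired somas. Optional dead somas
render saturated in the schematic phase image, which draws a 0.7-intensity
halo rim around each 0.5-intensity body so the 95%-of-max exclusion rule
has a realistic bright reference.

What the scenes do **not** emulate: point-spread functions, shot noise,
uneven illumination, phase-contrast optics, nucleus texture, or cell-shape
irregularity. Passing tests therefore demonstrate correctness of the
computations under their stated assumptions, not segmentation robustness on
real micrographs.

## Problem sizes and determinism

All spectral computations run on single 600 × 600 fields. Ensemble checks
(arrangement comparisons, detection precision/recall) use 20 independent
seeds per condition, sufficient to separate the compared means by an order
of magnitude more than their standard errors at these settings. Every
generator takes an explicit seed through `numpy.random.default_rng`; the
pipeline writes its seed and parameters to a JSON manifest, and a rerun
with the same manifest is byte-identical.

## Known limitations

* Fused nuclei are counted once (no declumping); merged-component behaviour
  is tested and documented rather than corrected.
* The white-noise NCF floor (≈0.088) and the discrete power-law value
  (0.5478) deviate from the idealized 0 and 0.5 on the finite grid, as
  derived above.
* The connectivity stage consumes manual or synthetic soma annotations; it
  does not segment somas from phase-contrast images.
* The study's absolute measured values (clustering factors of particular
  cultures, cell counts, µm² areas, percent connectivity changes) depend on
  the original micrographs and are not reproduction targets of the
  synthetic suite; the suite validates calibration anchors, invariances and
  ground-truth recovery.
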