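# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `cryoclem`, and what the synthetic-data validation does and does not
demonstrate about real specimens.

## Coordinate conventions

Points are column 2-vectors `(x, y)`. Image frames use 0-based coordinates
at pixel centres, x rightward, y downward, origin at the top-left pixel
centre; stage frames are metric (µm) with the same axis orientation. A
`Transform2D` maps source → target as `p ↦ M p + t`. These conventions are
fixed repository-wide; instrument vendors differ here, and any adapter to
real data must normalize to them first.

## Transform fitting

Similarity fits (isotropic scale × rotation, optional mirror) use the
closed-form orthogonal-Procrustes solution; affine fits use linear least
squares on the homogeneous design matrix. Degenerate geometry (condition
number > 1e8, coincident sources, collinear points for affine) raises
rather than returning silent garbage. Reflection handling: FM and EM
images may differ in handedness, so similarity fits accept
`allow_reflection` (default true for FM↔EM image registration); the fitted
determinant sign is the residual-minimizing one. With only two pairs and
reflection free, both handednesses fit exactly — this ambiguity is why the
bead-matching loop refits only on ≥ 3 matches and why the high-accuracy
tier requires the model minimum plus one pair (which also makes the
leave-one-out RMS defined).

Diagnostics: `rms_residual` is in-sample; `loo_rms` refits with each pair
held out and RMS-averages the held-out prediction errors. The
leave-one-out figure is the honest predictor of targeting error at a new
position and is what the prediction radius quotes (floored at a 50 nm
display radius; flagged, not fatal, above a 1 µm sanity ceiling).
Positions of interest outside the convex hull of the fiducials are flagged
`extrapolated`, since extrapolation inflates the prediction variance.

## Spot detection and localization

Detection filters with a scale-normalized Laplacian of Gaussian at the
expected PSF width and keeps local maxima above `median + min_snr × SD`,
with the SD estimated robustly (MAD × 1.4826) on 64-pixel blocks —
grid images mix bright support film with dark bars, and a single global
noise estimate under-thresholds the noisy film regions. A border of 2σ is
excluded (filter edge artifacts), and candidates closer than 2σ are merged
keeping the stronger. Defaults: `min_snr = 5`, fit-window halfwidth
`ceil(3σ)`, channel-coincidence radius 2 px; all config-overridable.

Localization refines each candidate with an isotropic 2D Gaussian plus
constant background (Levenberg–Marquardt). A fit is rejected when the
solver fails, the amplitude is non-positive, the centre leaves the window,
the fitted width strays outside 0.4–2.5× the expected PSF width (edges and
extended structures converge to much wider or needle-thin Gaussians), or
the amplitude/background pair is degenerate (amplitude > 1.5× the window's
dynamic range, or background below the window minimum) — the failure mode
of broad fits latched onto near-flat noise. The reported localization
uncertainty is the RMS of the x/y standard errors from the fit covariance;
on Poisson-noise spots it tracks the empirical scatter to within ~50%.
Electron-dense beads in EM frames are darker than background: the image is
inverted and run through the same pipeline, with the detection scale
matched to the bead diameter so 10 nm gold fiducials are not picked up at
the 100 nm bead scale. Z-stacks are reduced by maximum projection before
detection; per-plane fitting is out of scope. Gaussian fitting was chosen
over centroiding for its noise resistance; a centroid fallback would be a
small extension.

Classification: spots coincident within the coincidence radius in ≥ 2
channels are beads (multi-colour fiducials); spots only in the designated
signal channel are specimen signal; remaining single-channel spots are
rejected. Coincidence is resolved as connected components over
cross-channel links.

## Mosaics

Autofocus scores planes with the Brenner gradient and refines the peak by
parabolic interpolation through its neighbours (edge peaks return the edge
plane). The focus map is bilinear over the sampled scan lattice; missing
lattice nodes are filled from the global least-squares plane, which is also
used outside the sampled bounding box. Bilinear interpolation is exact on
planes, so grid tilt — the dominant real-world effect — is represented
exactly; curvature error scales with the lattice-cell-scale second
derivative.

Stitching refines each neighbour pair's stage-derived offset by a bounded
integer search (±12 px by default) maximizing the normalized
cross-correlation of the overlap, gated by a peak-ratio test (peak vs the
best value outside a ±3-lag neighbourhood, threshold 3): smooth or
featureless overlaps fail the gate and the pair is dropped. Accepted
integer shifts are refined to subpixel by upsampled phase correlation on
the exactly-aligned overlap (skipped when the integer-lag correlation is
already > 0.995, i.e. the data agree to numerical precision). The pairwise
measurements are reconciled by least squares over the pair graph; each
connected component is anchored at one tile's nominal position, so tiles
without any trustworthy overlap fall back to nominal placement without
contaminating the rest. Overlaps are feather-blended. Multi-channel scans
share one placement: secondary channels are assembled with the reference
channel's offsets — independent per-channel stitching would break
cross-channel spot coincidence at the subpixel level. The mosaic→stage map
is an affine fitted from placed tile centres against their nominal stage
positions. Default overlap fraction 0.10.

## Bead matching

Starting from the previous tier's transform, FM beads are mapped to the EM
frame and matched to EM beads by mutual nearest neighbour within a gate
(default 1 µm, 2 µm in the pipeline where the grid-wide error is larger);
the loop match → refit similarity → rematch runs to stability or 10
iterations, keeping the iteration with the most matches (ties broken by
RMS). A bead whose two nearest partners are equidistant within a 1e-6
relative tolerance is dropped as ambiguous, on either side, which makes the
matching symmetric under swapping the FM and EM roles. The gate must stay
below roughly half the bead spacing relative to the approximate
transform's error; beyond that, a consistent wrong assignment can lock in —
the automated analogue of picking the wrong bead pair by eye.

## Accuracy model

With centred independent per-axis normal errors (σₓ, σᵧ), the hit
probability for a square FOV of side F is
`(2Φ(F/2σₓ) − 1)(2Φ(F/2σᵧ) − 1)`; a Monte-Carlo mode cross-checks the
closed form. `min_fov_for_rate` inverts it by bisection to 1 nm, returning
the upper bracket so the returned FOV always meets the rate. Deviation SDs
are RMS **about zero** by default: the deviation is measured from the
intended target, and systematic bias is targeting error; `about_mean=True`
separates bias for diagnosis. Normality is assessed per axis by
Shapiro–Wilk and the smaller p-value reported. The chance-hit null models
objects as a spatial Poisson process: `P = 1 − exp(−density · F²)`.

At SDs of 227/256 nm the closed form gives 97.8% in a 1.24 µm FOV and
87.8% at 900 nm. The latter exceeds the 80% figure usually quoted for that
operating point; the closed form is reported as-is rather than adjusted,
since any additional failure modes (aggregates, failed acquisitions) are
counted, not modelled.

## Synthetic scenes

The generator emulates a vitrified EM grid region: 200- or 300-mesh
geometry (pitch/bar defaults 125/35 µm and 85/25 µm), multi-channel
fluorescent beads (100 nm default; brightness ∝ diameter³, so 50 nm beads
are 8× dimmer), 10 nm gold, and diffraction-limited signal sources, all
placed uniformly at random on open support film (rejection sampling;
failure after bounded retries raises). A configurable number of squares is
marked broken to serve as grid-wide landmarks. The ground-truth FM→EM map
is a similarity with rotation uniform in [0, 2π), reflection on by default,
scale ~1 between stage frames, and an optional shear term to exercise the
affine path. All randomness flows from one seed; renderers draw from
per-(scene, channel) substreams.

FM rendering: 0.13 µm pixels (a 179 µm field across a ~1400 px sensor) and
0.18 µm lateral PSF σ (axial 3× lateral) are generator defaults chosen as
realistic for a high-NA cryo objective — not measured values. Tiles are
Z-stacks (default 10 µm range, 1 µm step) on a 10%-overlap scan lattice;
objects sit at the per-square topography height (±1.5 µm); bars are
opaque; autofluorescence raises the film background in the green channel;
noise is Poisson shot plus Gaussian read. EM rendering: beads/gold as
soft-edged dark disks of their physical diameter (10 nm/px default), POIs
as fainter disks, smoothly textured film, Gaussian noise, bars mapped
through the inverse truth transform.

Not emulated: physical-optics PSFs and defocus blur (out-of-focus objects
dim axially but do not widen laterally), CTF and dose effects, ice
contamination and devitrification, bead aggregation, and stage drift.
Passing tests therefore demonstrate the correctness of the coordinate and
statistical machinery under controlled noise — not robustness to every
real-world imaging artifact.

## Problem sizes

Image-level validation runs on quarter-scale scenes (2×2 squares of
21.25 µm pitch, ~190 px tiles, 3-plane stacks, 25 beads per square —
matching the local bead density visible in typical medium-magnification
fields) so a full render–stitch–register loop completes in seconds; the
registration and statistics layers are additionally validated at full
scale at coordinate level. The 400-trial targeting simulation injects
50/20 nm FM/EM localization noise and a 230 nm per-axis per-acquisition
error emulating image-montage registration, the dominant inaccuracy of the
automated-acquisition tier; the hit rate it produces is checked against
the closed form within three binomial standard errors. The
post-acquisition simulation (100 replicates, 15 pairs, 20 nm per-side
noise) reproduces the ~10 nm RMS prediction error regime.

## Known limitations

- The navigator dialect covers point/polygon/map items with the minimal
  field set (Type, StageXYZ, GroupID, MapFile, MapScaleMat); all other
  keys are preserved verbatim but not interpreted.
- MRC I/O supports modes 0/1/2, little-endian, no extended headers.
- The stitcher does no illumination flat-fielding and no global bundle
  adjustment beyond the pair-graph least squares.
- Bead matching assumes a locally rigid (similarity) relation; deformable
  section registration is out of scope.
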