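# Methods

`pollenodt` simulates, end to end, a label-free 3D imaging experiment on
conifer (*Pinus*) pollen grains: optical diffraction tomography (ODT) of
oil-mounted grains, followed by refractive-index (RI) based morphometry and
rank-based comparison between strains. Because no raw instrument data for
such experiments are publicly deposited, the package generates its own
ground truth — synthetic bisaccate RI phantoms — and pushes them through a
physically explicit instrument model, so every downstream quantity can be
scored against a known answer.

## The phantom and what it emulates

A bisaccate grain is modelled as an ellipsoidal corpus bounded by a rigid
exine shell, a thickened dorsal cappa, two ventro-lateral air sacs (sacci)
whose walls are exine and whose lumina hold mounting medium, a ventral
germinal wrinkle carved between the sacci and lined with exine, and — in
whole grains — ellipsoidal starch granules in the cytoplasm. RI levels
follow what oil-mounted grains show under ODT: medium 1.52 (index-matching
oil), exine 1.53, cappa 1.54, corpus interior 1.508 (below the medium),
starch 1.53. Hollow shells set the interior to medium RI and carry no
starch.

Defaults place a ~21 µm grain (corpus semiaxes 10.5/10.0/9.5 µm) in a
128³ grid at 0.25 µm pitch (32 µm box) — large enough that 20 granules of
2–3 µm diameter can be placed with separations that survive reconstruction
blur, and small enough that every FFT in the pipeline is desk-scale. Real
grains reach ~45 µm; the geometry scales through `PhantomSpec` and the
grid settings.

Granules are placed largest-first by drawing up to 1000 candidate centers
and keeping the admissible candidate with the snuggest fit, under an
anisotropic surface-to-surface gap (0.5 µm lateral, 1.5 µm axial): the
axial point-spread function is several times wider than the lateral one,
so axially stacked granules need more room to remain countable. Placement
is deterministic under the spec seed.

Interfaces are anti-aliased by 2× supersampled rasterization and block
averaging — exactly volume-fraction weighting — so voxel-summed volumes of
analytic shapes converge to their closed forms (tested for spheres and for
the granule load) and surface areas carry no stair-step bias.

Strain populations scale every linear geometry parameter by an independent
unit-mean log-normal multiplier with the requested coefficient of
variation; granule placement re-randomizes per grain.

What the phantom does *not* emulate: exine micro-ornamentation (an optional
RI speckle stands in), birefringence, dispersion, and any chemical
specificity beyond RI. Passing tests therefore demonstrate that the
*pipeline* recovers known structure through the instrument physics, not
that real grains of a given species would yield these numbers.

## Instrument model

Illumination: coherent plane waves at 532 nm (not printed in the source
study; it is the unique common laser line that makes the quoted 166 nm
lateral resolution equal λ/(4·NA) at NA 0.8). The default scan is normal
incidence plus three rings of tilts at 0.95/0.7/0.4 of the illumination NA
(48/32/16 angles, 97 total). A single-ring scan is available
(`make_circular_scan`) but sweeps the Ewald cap along one circle only,
sampling the reachable frequency support as a sparse sheaf of thin sheets;
the multi-ring default gives the inversion a solid support to stand on.
Scan vectors are snapped to the simulation grid's frequency lattice so
tilted plane waves are exactly periodic.

Propagation is multi-slice beam propagation: per-slice phase screens
`exp(i2π(n−n_m)Δz/λ)` alternated with angular-spectrum steps in the
medium, then numerical refocus to the volume-center plane and a hard
low-pass at the detection NA. This includes multiple forward scattering,
so the linearized inverse model downstream is a genuine approximation, not
an inverse crime. Energy is conserved to <0.5% before NA filtering;
mirroring phantom and illumination mirrors the field to machine precision.

Off-axis holograms are `|U + R|²` with a unit reference tilted to a
carrier of ~4.8 cycles/µm (>3 detection bandwidths, below the camera
Nyquist rate at 4× camera oversampling), plus optional additive Gaussian
noise and clipping at zero. Matching sample-free background frames are
always simulated — the retrieval normalizes by them rather than assuming
an ideal reference.

## Field retrieval

Demodulation crops a circular sideband of radius NA/λ around the carrier,
recenters it and inverse-transforms; the crop is a hard mask, so
synthesis→demodulation round-trips band-limited fields to machine
precision (property-tested). Fields are retrieved on a 2× finer lateral
grid than the reconstruction volume (same field of view): relative to a
tilted illumination the scattered spectrum reaches NA/λ + |k_i| ≈ 2.9
cycles/µm, beyond the volume grid's Nyquist range, and must be resolved
rather than aliased before the Ewald mapping truncates it.

Sample/background ratios are unwrapped by transform-based least-squares
(DCT/Poisson, Neumann boundaries) — deterministic and seed-free, exact for
smooth pollen phase maps — and combined into Rytov data `ln A + iφ`.
Pixels with vanishing background amplitude are masked, inpainted by
nearest neighbor, and reported in QC.

## Reconstruction

Per-angle Rytov spectra are placed on Ewald caps `K = k_s − k_i` with the
Fourier-diffraction weight −4πi·ν_z, nearest-voxel gridded with
count-averaging of overlaps. Before inversion, two conditioning steps act
on the accumulated spectrum:

* **axial gap interpolation** (`gap_fill`, default 6 samples): narrow
  unmeasured gaps between adjacent cap sheets are bridged by linear
  interpolation along K_z; one-sided extrapolation is never performed, so
  the true missing cone is not bridged;
* **axial apodization** (`axial_taper`, default 0.1 cycles/µm): the
  support ends abruptly along K_z at the missing-cone boundary, and that
  hard truncation rings axially with ~22% sidelobes — enough for the
  bright shell to mask interior granules. A raised-cosine rolloff at each
  column's support edge trades a slight axial resolution loss for strongly
  suppressed ringing. Tests that probe the raw transfer function (weak-
  sphere recovery, linearity) disable it.

The RI map follows from `n = √(n_m² + V/k₀²)`, clamped at the vacuum
index; the clamped fraction and the imaginary residual are QC outputs.

Missing-cone regularization is Gerchberg–Papoulis: alternate replacing
measured spectrum samples with their measured values and enforcing
real-space constraints — an RI lower bound and, crucially, an object
support. The default lower bound is 1.0 (vacuum), *not* the medium: the
corpus interior genuinely lies below the medium RI, so a medium-level
bound would erase real structure; consequently the bound almost never
activates and the support carries the information. The pipeline runs two
passes: an unregularized inversion is segmented to obtain the grain
support (dilated 5 voxels, optionally further along z), then GP runs with
that support (60 iterations, tol 1e-7; both convex projections, so the
update norm is non-increasing). Over-iterating (≳150 sweeps) starts to
degrade granule separation; 60 is the operating point.

Instrument characterization mirrors standard practice: RI sensitivity is
the standard deviation of the reconstructed RI over a known-medium region
(the noise-injection test calibrates hologram noise to reproduce an
instrument-grade 5×10⁻⁴), and the lateral resolution estimate is the
Abbe-type half-period of the widest filled lateral frequency, with
λ/(4·NA) = 166 nm as the theoretical limit at the defaults.

## Morphometry

Grain occupancy: threshold `|n − n_m| ≥ δ`, morphological closing (radius
2 voxels, grown adaptively to 5 if the grain falls apart into nearby
comparable pieces, as happens when a thin saccus wall reconstructs
weakly), interior hole-filling (so the sub-medium corpus interior and the
medium-filled lumina count), largest component. The threshold must exceed
3× the medium-RI noise, estimated robustly (1.4826·MAD of the sample-free
boundary shell) so deterministic ringing does not masquerade as noise.
Default δ is 0.005 on clean maps and 0.003 in the pipeline, where
recovered contrast is roughly halved.

Volume is voxel count × voxel volume (reported in pl); surface area is
the triangulated isosurface (marching cubes at 0.5 on the hole-filled,
σ=1 voxel smoothed indicator — voxel-face counting would inflate a
sphere's area ~1.5× and break the sphericity semantics); the sphericity
index is `SI = (36πV²)^{1/3}/S`, capped at 1.0 in records against <1%
mesh undershoot for near-spheres.

Starch: voxels with `n ≥ n_m + δ_starch` (default 0.004 — granule peaks
recover to about n_m+0.005 at desk scale, and 0.004 is still 8× the
5×10⁻⁴ sensitivity) inside the occupancy. Starch and exine share RI, so
they are told apart morphologically: a 1-voxel opening severs blur
bridges; components are kept only with equivalent diameter in
[1, 6] µm (the exine network, including the inter-saccus screens that
defeat any erosion-band rule, is far larger); a compactness filter (max
inscribed radius ≥ 0.45 of the equivalent radius) rejects the arc- and
sheet-shaped ghosts that residual ringing leaves; an EDT watershed splits
touching granules. Mass is volume × dry-starch density, default 1.5
pg/µm³ (≈1.5 g/cm³, the standard literature value), configurable.

Two documented analysis profiles exist because two goals pull the support
constraint in opposite directions. The **granule profile** (defaults)
keeps the axial support tight, which suppresses ghosts and preserves the
20/20 granule count on the default phantom. The **volume profile**
(`support_delta=0.0035`, final `delta=0.002`, `support_dilation_axial=6`)
gives the regularizer generous axial room, which protects axially
flattened grains — the missing cone's worst case — from support
truncation; it is the right tool when grain size, not content, is the
quantity of interest, and is what the population rank-correlation test
uses.

## Statistics

Two-sided Mann–Whitney U with `U = min(U₁,U₂)` and midrank ties; exact
p by full enumeration of the `C(n₁+n₂, n₁)` labelings for pooled sizes up
to 14 (p = probability of a min-U at most the observed one), otherwise the
tie-corrected, continuity-corrected normal approximation. Star codes
follow the usual convention (p<0.05 *, <0.01 **, <0.001 ***, <0.0001
****). Pairwise p-values are reported raw — matching common descriptive-
morphometry practice — with an optional Holm adjustment behind a flag and
a log note. Summaries are mean ± sample SD (n−1). Whether the original
analysis was exact or asymptotic, one- or two-sided, is not stated in the
source; two-sided is assumed.

## Numerical choices and degenerate inputs

Frequencies are cycles/µm, spectra are stored DC-centered, and all
centered-origin FFTs carry explicit half-grid phase factors (a silent
origin mismatch scrambles the inter-cap phase coherence). Granule
rasterization never overwrites shell or lumen voxels. Empty masks,
hollow grains, single-element groups, carrier/Nyquist violations,
oversized geometry and unplaceable granules all raise or flag explicitly
rather than returning garbage.

## Problem sizes

Simulation-backed tests run at 64³–96³ with a reduced two-ring scan; the
flagship grain-recovery test runs the full default configuration (128³,
97 angles, 60 GP sweeps), and the population test runs ten 96³ grains.
These sizes are the package's chosen desk scale; everything scales up
through configuration.

## Known limitations

* Axially facing interfaces (dorsal/ventral shell caps) are attenuated by
  the missing cone for any inversion in scope; shell RI is therefore read
  from laterally facing walls, and hollow-shell volumes are less reliable
  than whole-grain volumes (no interior contrast to anchor the fill).
* Recovered contrast at desk scale is roughly half of truth away from the
  well-sampled lateral directions; thresholds are set accordingly and are
  not transferable to data of different quality without re-calibration.
* At aggressive scale-downs (~8 µm grains in 16 µm boxes) reconstruction
  ripple can leave starch-like specks in hollow grains an order of
  magnitude below real granule loads; at the default scale the hollow
  phantom reports exactly zero.
* The forward model omits partial coherence, polarization, aberrations
  and camera quantization; the inverse model is first-Rytov with GP-class
  regularization (no TV, no multiple-scattering inversion).
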