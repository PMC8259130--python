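# Methods

This note states the model implemented by `besselflow`, the default
parameters and their rationale, the numerical choices, and what the
simulator does and does not emulate. Every empirical number quoted here is
computed by the test suite or `scripts/acceptance.py`.

## 1. Optical model

### Beam

The illumination is a Bessel–Gaussian focus: transverse field
`E(r) ∝ J0(k_r r) · exp(−r² / w0²)`, intensity `E²`. Its long axial focus
is the reason this architecture can image flowing cells without an
autofocus; its price is a set of concentric sidelobes.

For a slit-integrated line-scan system, the beam is well approximated by a
**comb of weighted delta functions** at the extrema of J0 (the zeros of J1,
since J0′ = −J1): between extrema the integrand oscillates and largely
cancels, while each extremum contributes a phase-matched lobe. The comb
weight of the l-th extremum at radius `u_l / k_r` is

```
a_l² = J0(u_l)² · exp(−2 u_l² / (k_r w0)²),
```

mirrored to negative offsets and normalized so the central lobe has weight
exactly 1. At defaults, the one-sided sum of sidelobe weights is 0.284 —
strictly below 1/2, which is what later makes the mixing operator
diagonally dominant and the inversion stable.

Extrema are located by `scipy.special.jn_zeros` (zeros of J1) with a
`brentq` polish; a dense-scan oracle in the tests confirms positions to
1e−8.

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `wavelength` | 0.488 | µm | typical blue excitation line |
| `k_r` | 1.87727 | rad/µm | chosen so the J0² main-lobe FWHM is 1.2 µm, the middle of the 1–1.5 µm band such beams show in practice; the universal constant FWHM·k_r = 2.252728 is computed at import by root-finding on J0(x)² = 1/2 |
| `w0` | 10 | µm | Gaussian apodization waist; sets how fast sidelobes decay |
| `n0` | 1.33 | — | aqueous buffer |
| `sidelobe_span` | 20 | µm | comb truncation radius; 11 one-sided extrema; widening by 50% changes the one-sided weight sum by < 1e−3 (tested) |

## 2. Phantoms

Objects are 2D transmission maps `f(z, y) ∈ [0, 1.3]` on a 0.08 µm grid,
background 1.

* **Beads**: dark rim annulus (default transmission 0.5, width
  min(0.8 µm, R/4)), body 0.75, optional bright centre 1.15 (diameter d/4,
  smoothstep-blended) modelling the lensing bright spot real polystyrene
  beads show in transmission.
* **Cells**: smooth disk (0.85) with seeded random granules, alternately
  brighter/darker than the body by `granule_contrast`. Granule centres
  keep ≥ 1.5 granule-radii separation; infeasible packings raise.
* **Algal colonies**: 1/2/4/8 ellipses (long axis along flow) side by side
  across the scan axis.

Transmission may also be derived from an index contrast Δn via the
two-interface Fresnel formula `f = 4 n0 (n0+Δn) / (2 n0 + Δn)²`
(Δn = 0.27 polystyrene in water → f = 0.9915: real beads are nearly
invisible by refraction alone, which is why the phantom specifies effective
transmission levels directly).

Scenes are seeded mixtures: per-class counts, diameters normal with given
CV (clipped at ±3 CV), speeds uniform in 10–25 cm/s, lateral offsets
N(0, 1.5 µm) clipped at ±4 µm, arrival spacing uniform in 500–620 µs.
`numpy.random.SeedSequence` spawning gives per-object independent streams;
identical (classes, seed) give byte-identical scene JSON.

## 3. Forward model

Sample i of scan n maps to scan position `y = (t mod T) · fov_y/T` and flow
position `z = z0 + v·t`. Defaults: scan period T = 5 µs over
fov_y = 40 µm (scan speed 8 m/s), sample rate 25 MS/s → 125 samples per
scan at 0.32 µm pitch. The scan sweep is ≥ 30× faster than any allowed
flow speed, so each scan is treated as an instantaneous line at the
object's current z — at 20 cm/s the object advances 1 µm per scan.

Per scan line:

1. the phantom is averaged over the slit height (1.5 µm, 9-point linear
   interpolation quadrature along z),
2. the comb is applied as a shift-and-sum over grid-snapped sidelobe
   offsets (shared `grid_comb` primitive — see section 4 below),
3. the result is normalized by the total comb weight (baseline 1),
4. a fixed per-scan multiplicative background ripple (4 Fourier harmonics,
   amplitude 2%, seeded) models slit/illumination non-uniformity,
5. white Gaussian noise (σ = 1%) is added.

A second channel emulates a **two-slit velocimeter**: two Gaussian dips
(depth 0.4, σ = width/4) at arrival ± Δt/2, where Δt = 20 µm (slit
separation at the object plane) divided by the object speed.

## 4. Reconstruction

Each measured scan is a linear mixture of the transmission line with the
comb. On the extended grid — 125 in-field samples plus
`ceil(20/0.32) = 63` padding samples per side — the mixing operator is a
**251×251 symmetric, unit-diagonal, banded Toeplitz matrix**: entry (i, j)
carries the comb weight whose offset rounds to `|i−j|` grid steps.
Sidelobe offsets are snapped to the grid by the same `grid_comb` function
used by the forward shift-sum, so the matrix-product and shift-sum forms
agree to 1e−12 by construction (tested against 50 random phantoms).

Because the one-sided comb weight sum is < 1/2 the matrix is strictly
diagonally dominant; its condition number at defaults is **2.31**, so the
inversion amplifies noise by at most a small factor (measured output RMS
< 3× input σ over 100 noise-only scans). Should a non-default beam break
dominance, the solver falls back to a ridge-regularized least-squares
solve and flags the matrix.

Objects are confined to the field of view, so the out-of-field
transmission is known background (f = 1). The in-field line is recovered
by solving the in-field block exactly with the off-field coupling moved to
the right-hand side:

```
f_in = T_ff⁻¹ (J·S − T_fo·1),    S = total comb weight.
```

The LU factorization is cached on the matrix; the forward→inverse round
trip is exact to ~2e−15 (asserted ≤ 1e−9 in the acceptance tests).

Pipeline order: background ripple removal (median pattern over
object-free scans, two-pass object masking) → event detection (runs of
≥ 2 scans dipping below 1 − 0.08, padded by 2 clean scans, merged when
overlapping) → per-scan inversion → stacking at flow pitch
`v · T` (µm per scan), with optional bilinear resampling to square pixels
for display.

## 5. Waveform features and sorting

Features are computed from the waveform directly (no image needed), as a
real-time sorter would:

* **Speed v**: the two velocimeter dips are located by argmin with an
  exclusion window and refined by parabolic interpolation;
  `v = 20 µm / Δt`. Recovery is within one sample of timing resolution
  across 10–25 cm/s (tested). Events without two qualifying dips are
  reason-coded and excluded from sorting (they cost yield, never purity).
* **T1** (length): the per-scan envelope depth is thresholded at
  `max(4σ, 0.005, 0.1 · peak depth)` and the first/last crossings are
  linearly interpolated. The envelope-scaled term keeps the endpoints on
  the steep flank of the envelope rather than extrapolating into its
  zero-depth tail. `L = T1 · v` recovers bead diameter + slit height
  within one scan of travel across the full size/speed grid (tested).
* **T2** (width): per scan, the contiguous region below
  `max(4σ, 0.005, 0.2 · scan depth)` containing the scan minimum, edges
  sub-sample interpolated; `W = max T2 · v_scan`. The depth-scaled term
  excludes the first-sidelobe echo of a dark object (≈ 5% of the dip
  depth, present regardless of noise), which a fixed noise-based threshold
  would merge into the width. Recovery is within 2 pixels (0.64 µm) of the
  true diameter (tested).
* **N** (granularity): positive peaks above `1 + max(4σ, 0.02)`
  (`scipy.signal.find_peaks`, minimum 2-sample separation), counted only
  within the T1 scan span so baseline noise outside the object cannot
  contribute. N correlates with the phantom granule count
  (Spearman ρ > 0.8 over 50 seeded cells, tested).

Speed multiplication (`L = T1·v`, `Nv = N·v`) removes the 2.5× spread the
flow-speed range would otherwise impose on temporal features (tested:
CV of L is > 5× smaller than CV of T1 across random speeds).

**Gating** is axis-aligned: fixed bounds, or a 1D threshold at the KDE
density valley between the two most prominent modes (an Otsu variant is
provided as an alternative). **Metrics**: purity = TP/(TP+FP),
yield = TP/(TP+FN), enrichment = target:background odds after sorting over
odds before.

### Demo mixtures

| config | classes | gate |
|---|---|---|
| `bead_mixture_config(7, 10)` | 200 + 200 beads, CV 3% | valley on `(T1·v)(T2·v_scan)` |
| `bead_mixture_config(7, 15)` | 150 + 150 beads | same |
| `leukemia_config()` | 20 granular 13 µm cells (10 granules, contrast 0.4) in 1000 smooth 9 µm cells (3 granules, contrast 0.1) | `L ∈ [12, 25] µm` and `Nv ≥ 40` |
| `algae_config()` | 30 four-cell colonies in 150 small organisms | `L ≥ 8.5 µm` |

The cell class parameters are simulation assumptions (no measured
size/granularity statistics exist for the biological analogues); they are
stated in the config and chosen to be separable the way the corresponding
real samples are.

## 6. What the simulator does not emulate

* No 3D optics: the beam is a 1D comb, the slit a box average; defocus,
  scattering, and absorption–vs–phase contrast are all folded into the
  effective transmission levels.
* No shot noise or PMT/amplifier dynamics — additive white Gaussian noise
  only, with a fixed multiplicative per-scan ripple.
* Objects arrive one at a time (scene generation enforces non-overlap);
  coincidences and doublets are out of scope.
* No actuation physics: "sorting" is the gate decision itself; droplet or
  valve latency, reserve buffers, and real-time compute budgets are not
  modelled.
* The flow is ideal: constant per-object speed, no lateral migration, no
  rotation during transit.

## 7. Numerical choices

* All stochastic stages take explicit seeds; a run is fully determined by
  (config, seed) and outputs embed a canonical-JSON SHA-256 config hash.
* The comb/grid snapping is the single shared primitive between the
  forward model and the transfer matrix — their agreement is structural,
  not numerical coincidence.
* Toeplitz assembly via `scipy.linalg.toeplitz`; LU via
  `scipy.linalg.lu_factor` cached per matrix; condition number via
  `numpy.linalg.cond`.
* Phantom rendering at 0.08 µm (quarter of the scan pitch) keeps rim and
  granule features resolved; `make_bead` rejects pitches coarser than the
  rim width.
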