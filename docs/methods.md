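# Methods

This note documents the models, the synthetic-data generators, the
numerical choices, and the limitations of the package. Units follow the
field's conventions: viscosity in cP (1 Pa·s = 1000 cP), shear in
dyn/cm² (1 Pa = 10 dyn/cm²), TEER in Ω, capacitance in nF, lengths in
µm inside image-derived tables and SI internally.

## Microrheology

### Model

Tracer beads of radius a = 100 nm (200 nm diameter) embedded in mucus
perform thermal motion whose ensemble mean squared displacement encodes
the medium's rheology. Per particle, the time-averaged MSD over all
ordered frame pairs is

MSD(τ) = ⟨|r(t + τ) − r(t)|²⟩_t,

averaged without weights over the particles of a region (the protocol
records ≥ 8 regions per condition; condition-level statistics aggregate
region-level estimates). The log–log slope α of MSD ∝ τ^α selects the
branch:

* **α > 0.95 (strict): viscous.** MSD = 2·n·D·τ with n = 2 dimensions;
  D is fitted through the origin by least squares (slope
  Σ τ·MSD / (4 Σ τ²)) and η = k_B·T/(6π·D·a). The boundary value
  α = 0.95 itself classifies as viscoelastic.
* **otherwise: viscoelastic.** The generalized Stokes–Einstein relation
  gives the creep compliance J(t) = 3π·a·MSD(t)/(2·k_B·T); a Maxwell
  element (spring G in series with dashpot η) has J(t) = 1/G + t/η, so
  an ordinary least-squares line yields G (inverse intercept) and η
  (inverse slope). Non-positive slope or intercept raises with a
  diagnostic — a non-positive intercept usually means the data are
  purely viscous and belong to the other branch.

### Parameters

| parameter | default | why |
|---|---|---|
| frame rate / duration | 20 frames/s, 5 s (100 frames) | the MPT acquisition protocol |
| particle radius | 100 nm | tracer bead size |
| temperature | 298.15 K | acquisitions after 15 min equilibration at room temperature |
| max_lag_fraction | 0.25 | long lags average few, highly correlated pairs; beyond ~¼ of the track the estimate is noise-dominated |
| min track length | 10 frames | shorter tracks carry almost no time-averaging information |
| α fit range | all retained lags | no separate window is prescribed; exposed as a parameter |

### Tracking

Detection: connected pixels above a threshold (default: median + 5σ of
the frame, σ from the median absolute deviation — a robust rule for
sparse bright spots on noisy background; Otsu misfires on such images),
size-filtered, localized by the intensity-weighted centroid (sub-pixel).
Linking: the proximity principle, implemented as greedy matching in
ascending pair distance with a hard gate (`max_displacement`, sensibly
~5× the RMS Brownian step), deterministic tie-break by (frame, detection
index). A missed detection terminates the track — no gap closing — and
unmatched detections seed new tracks. Global optimal assignment
(Hungarian) would differ only when beads approach within the gate; the
greedy rule is the faithful reading of "closest positions in successive
frames". No drift correction is applied by default (acquisitions on an
active optical table); coordinates use pixel centers at integer
positions, origin top-left, x rightward, y downward.

## Synthetic bead motion

* **Viscous media:** per-axis Gaussian increments of variance 2·D·Δt
  with D = k_B·T/(6π·η·a).
* **Maxwell media:** positions are drawn from a zero-mean Gaussian
  process with covariance C(t, s) = [M(t) + M(s) − M(|t−s|)]/2 per
  axis, where M is the per-axis target MSD
  (2·k_B·T/(3π·a))·(1/G + t/η)/2 and M(0) := 0 on the displacement law.
  With this convention E[(x(t) − x(s))²] equals the Maxwell target at
  *every* discrete lag, including the elastic plateau 2k_BT/(3πaG) as
  τ → 0 — equivalently, Brownian motion plus an i.i.d. Gaussian nugget.
  A mechanistic trap model is unnecessary: the analyses only see the
  MSD, and the covariance construction controls it exactly. Cholesky
  factorization with an escalating diagonal jitter (warned) guards
  against numerical indefiniteness.
* **Localization noise:** additive Gaussian on positions, default
  20 nm — a typical centroid precision for this bead size and optics;
  no measured value exists for the original setup, so the default is
  declared, not inferred. It is recorded in the ground-truth sidecar.
  The through-origin D fit over long lags makes the induced MSD offset
  (4σ² ≈ 1.6×10⁻³ µm²) a <1% viscosity bias even at 33 cP.
* **Video rendering:** Gaussian spots (σ = 1.3 px) of amplitude
  snr·√background on a constant background with Poisson shot noise;
  ground-truth pixel positions are returned as a sidecar table.

What the generators do **not** emulate: spatial heterogeneity of mucus
(every particle sees the same medium), bead–mucus chemistry,
out-of-focus loss, photobleaching, stage drift. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
statistical model, not robustness to all real-world imaging artifacts.

## Impedance

The epithelium's equivalent circuit is
Z(ω) = R_sol + 1/(jωC_e) + R_teer/(1 + jω·R_teer·C_mem). The electrode
interface is modeled as an ideal series capacitance; a constant-phase
element would be the natural extension but is not needed for the
synthetic protocol. Fitting is nonlinear least squares on stacked
(Re, Im) residuals — complex fitting, since modulus-only fitting
discards the phase information that separates the two capacitances —
weighted by 1/|Z| so the low-impedance decades are not drowned by the
electrode branch, with positivity enforced by optimizing
log-parameters (Levenberg–Marquardt, tolerances 10⁻¹⁵, so noiseless
round-trips recover parameters to machine precision). Initialization
from asymptotes: R_sol from |Z| at the highest frequency; C_e from
Im(Z) at the lowest; R_sol + R_teer from Re(Z) at the frequency of
minimal |Im(Z)| (between the corners, where relative noise is
smallest — the low-frequency end is useless because the electrode
capacitance dominates |Z| there); C_mem from the half-rise corner. A
fitted R_teer below 10⁻⁶·R_sol marks an unidentifiable epithelial
branch (e.g. a bare resistor) and raises. Measurement-protocol constants
(0.3 V bias, 10 mV amplitude, 3 readings) are metadata only. The Bode
modulus readout interpolates |Z| log-log at 12 Hz.

## Chip fluidics

### Geometry reduction

The lower block carries a 15 × 4 × 1.5 mm feed channel, a central
hexagonal pool (printed surface 2.08 cm², volume 0.312 cm³) and a
mirror-image outlet channel; the porous insert (6.5 mm diameter) sits
above the pool. Only the pool's area and volume are printed, so the
pool depth is volume/surface = 1.5 mm (equal to the channel height —
the slice is a flat strip), the streamwise pool extent is the
across-flats width of the regular hexagon of that area (≈ 15.5 mm), and
the effective spanwise width is area/extent (≈ 13.4 mm), preserving the
plan area. The 3D device is thus reduced to a 2D vertical mid-plane
slice with piecewise-constant effective width; this buys a fast, fully
testable solver at the cost of spanwise detail (see Limitations).

### Flow

Steady incompressible Stokes flow (Re ≈ 0.17 at 40 µL/min, asserted
≪ 10) on a staggered MAC grid, default 364 × 24 cells (≥ 10 cells
across the height are required). The spanwise width w(x) enters the
continuity equation, (w·u)_x + w·v_z = 0, so the volumetric flow rate
is conserved through width changes; at a width jump the face width is
the opening min(w⁻, w⁺). Boundary conditions: prescribed parabolic
inflow normalized to carry exactly Q, no-slip top (membrane) and bottom
walls with quadratic-extrapolation ghosts (a parabolic profile is then
discretely exact, which is why the straight-channel oracle
τ = 6µQ/(w·h²) is matched to <0.1%), fully developed outflow with zero
reference pressure. The saddle system is row-equilibrated and solved by
sparse LU. Wall shear uses a second-order one-sided derivative through
the wall zero. The fluid is the culture medium approximated as water
(µ = 10⁻³ Pa·s, ρ = 1000 kg/m³).

### Oxygen

Finite-volume upwind advection–diffusion (D = 3×10⁻⁹ m²/s, inlet
0.22 mol/m³, advective outflow, impermeable walls) with the
Michaelis–Menten sink R = V_max·ρ_cell·c/(K_m + c)
(V_max = 3.42×10⁻¹⁶ mol/(cell·s), K_m = 0.214 mol/m³,
ρ_cell = 7.5×10¹³ cell/m³) restricted to a 20 µm tissue layer beneath
the membrane across the insert footprint. Within the slice the sink is
weighted by the chord of the circular footprint at each x, so the
integrated tissue volume equals the true π·r²·layer. The layer is
applied to the top cell row scaled by layer/cell height; the mild
nonlinearity is resolved by Picard iteration. The conservative
discretization closes the flux budget (inlet − outlet = consumed) to
round-off, and concentrations below −10⁻⁶ of the inlet value raise a
resolution error. The membrane is a no-slip wall for flow (0.4 µm
pores, negligible through-flow at ALI) but transparent to the tissue's
oxygen uptake.

### Readouts

Membrane shear: µ·∂u/∂n on the pool's top wall, reported in dyn/cm²;
its coefficient of variation over the insert footprint quantifies
uniformity. At the default operating point the model gives
~1.3×10⁻³ dyn/cm² (CV < 10⁻²), a sub-membrane speed (sampled 50–150 µm
below the membrane, the near-wall band a cell layer experiences) of
~1.2×10⁻⁵ m/s, and a minimum oxygen of ~0.192 mol/m³ — the gentle,
homogeneous, well-oxygenated regime the chip was designed for.
Comparing feed-channel widths (4 mm vs 1 mm at equal flow rate), the
narrow channel's entrance jet leaves a far less uniform shear field
over the pool (CV ≈ 0.75 vs ≈ 0.18), the fluid-dynamic reason the wide
channel is the right design.

## Ciliary beat frequency

ROI mean-intensity traces at 100 frames/s (grayscale conversion by
channel averaging); CBF = peaks/duration with peak prominence ≥ 0.5 ×
trace SD (no threshold is prescribed by the workflow this mirrors; half
the SD rejects noise ripples while keeping genuine beats). The estimate
is cross-checked against the dominant periodogram frequency; >20%
disagreement flags the result, as do absent peaks (CBF 0) and estimates
at/above Nyquist. A line-kymograph view is provided for parity with the
plugin-style workflow. A simulated 8 Hz beat needs frame rate > 16
frames/s; the generator refuses undersampled requests.

## Morphometry and thickness

Marker abundance: thresholded marker area (µm², default Otsu with
manual override) divided by the nucleus count (connected components
above threshold and minimum area; optional distance-transform watershed
for touching nuclei, off by default). Shape metrics on label masks
(stand-ins for manual single-cell selection): area, aspect ratio =
major/minor axis of the moment-matched ellipse, circularity =
4π·area/perimeter² clipped to 1 (digitized perimeters of small discs
overshoot slightly); roundness-vs-circularity naming is resolved by
adopting these standard definitions. Mucus thickness from a two-channel
z-stack: the nuclear (blue) slab's top is the highest plane whose
in-plane coverage exceeds 1% (default; the original readout was visual
3D inspection), the bead (red) layer's bottom is the lowest such plane,
thickness = difference floored at 0. Coverage-based detection makes the
readout invariant to global intensity scaling when thresholds are
automatic. The synthetic two-layer stack rounds off-grid gaps to the z
step (warning; rounded truth recorded); z spacing 0.25 µm resolves the
condition-level gaps 9.75/14.8/39.4 µm to within one step.

## Pipeline and reproducibility

Every stage seed derives from a single master seed by fixed offsets;
fixed seed + configuration reproduce all outputs bit-identically
(asserted in tests byte-for-byte on the report and stage files).
Hypothesis testing between conditions (ANOVA, Kruskal–Wallis) is
deliberately a thin pass-through to standard routines — it is reporting,
not a contribution of this package.

## Problem sizes

Defaults were chosen so the full validation cycle runs in minutes on a
single core: 364 × 24 cells for the chip solve (the shear and oxygen
readouts move < 5% under 2× refinement), 500 particles × 100 frames for
recovery fixtures (viscosity sampling error ~2–3%), 100-seed ensembles
for the impedance noise study, 50-seed ensembles for CBF noise.

## Limitations

* The fluidics model is a width-averaged 2D slice: it cannot represent
  spanwise (y) flow structure, so the channel-width comparison reflects
  streamwise entrance development only, and absolute shear/velocity
  carry the reduction's geometric idealizations (the readouts agree
  with the design's full-3D values to within a factor of ~2).
* The tissue oxygen sink uses the printed volumetric cell density in a
  20 µm layer; a flux boundary from a seeded cell count is a supported
  alternative via the layer parameters but not the default.
* Tracking has no gap closing and no drift correction by default;
  dense fields where beads approach within the linking gate will
  truncate or swap tracks.
* The viscoelastic generator reproduces the Maxwell MSD law exactly but
  is not a mechanistic model of mucus microstructure; frequency-domain
  moduli (G′/G″) and heterogeneity analyses are out of scope.
* Automated segmentation of single cells in dense epithelium is out of
  scope; shape metrics expect externally provided label masks.
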