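# Methods

This note documents the models behind `dectspr`, the assumptions they make,
the parameters that matter, and the design decisions taken where the
underlying publications leave the choice open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Photon physics and ground truth

All attenuation in the pipeline derives from one packaged elemental table
(`data/elements_synthetic.json`): partial mass attenuation coefficients
(photoelectric, coherent, incoherent; cm²/g) for 25 elements covering
Z = 1–54, on a 30–150 keV grid in 5 keV steps. The table is **synthetic**:
it is computed by `scripts/generate_physics_tables.py` from standard
analytic models — Klein–Nishina incoherent scattering reduced by a
screening-style incoherent scattering function, Thomson coherent scattering
with a Thomas–Fermi-like screened form factor, and a smooth
`Z^4.62 / E^3.1` photoelectric power law whose global constant is anchored
to water's well-known total of 0.2683 cm²/g at 40 keV. The resulting water
totals land within ~1–3% of measured compilations across 30–150 keV, and
the per-electron scattering term varies by only ~14% over Z = 6–20, the
premise of the effective-atomic-number formalism. There are **no
absorption edges** (iodine and barium K-edges fall inside the grid but
those elements appear only as traces), and no claim of elemental accuracy
beyond these structural properties; everything downstream (forward models,
ground truths, basis tables) uses the same data, so the pipeline is
self-consistent by construction.

Mixtures follow the mass-fraction rule with log–log cubic interpolation in
energy. Ground truths per material: relative electron density from
`ρ·Σ(w_i Z_i/A_i)` normalized to water; `ln I` by Bragg additivity over
electron fractions; effective atomic number as the exponent-`n` power-law
mean (n = 3.1 where a convention is needed); SPR through the Bethe ratio
at 100 MeV protons (β² from relativistic kinematics with a 938.272 MeV
proton rest energy) against I_w = 78.73 eV.

Elemental I-values are ICRU 37, except that the seven elements H, C, N, O,
P, Cl and Ca are shifted uniformly in ln-space so that Bragg additivity on
water reproduces **exactly** 78.73 eV (the adjusted-literature convention
the reference value comes from; the exact adjusted elemental values are
not published alongside it). The shift is recorded in the data file.

The 73-entry reference-tissue library (`data/tissues_synthetic.json`) is a
nominal stand-in built from a four-component model (water, lipid, protein,
carbohydrate, hydroxyapatite mineral, salt ash) with literature-style names
and densities; the phantom inserts (`data/inserts_synthetic.json`) are nine
nominal tissue surrogates whose two bone inserts carry 200 and 800 mg/cm³
hydroxyapatite loadings. Neither table claims fidelity to any vendor's
proprietary compositions.

### A note on the Yang line and water

The piecewise-linear `ln I(Zeff)` parametrization (slopes 0.120 / 0.081,
intercepts 3.407 / 3.514, branch boundary assigned to the upper branch at
Zeff = 8.5) is used exactly as published. Evaluated at water's
Jackson–Hawkes-implicit EAN (≈7.43 on the packaged tables) it yields
I ≈ 73.6 eV, while the Bethe ratio normalizes to I_w = 78.73 eV; water —
an outlier above the tissue I-vs-Z trend — therefore maps through the VMI
chain with an inherent ≈ +0.8% SPR offset (a smaller version of the same
offset exists with measured cross sections). Tissues, whose
Bragg-additivity I values sit near the Yang line, map within 1%.

## The three mappers

**VMI pair.** Voxels are segmented on a 74 keV reference VMI into lung
(< −200 HU), soft ([−200, 150] HU, boundaries inclusive) and bone
(> 150 HU); each class has an assigned VMI pair. CT numbers are converted
to attenuation relative to water (`(CT#+1000)/1000`, clamped at zero below
−1000 HU with a warning), then multiplied by water's per-electron cross
section at the respective energy so the two-energy consistency equation
holds in per-electron units. The scalar solver minimizes the squared
(ratio-scaled) residual with SLSQP from Zeff = 5 within [4, 54]
(tolerance 10⁻⁸, grid-scan fallback); volume mapping uses an equivalent
precomputed monotone table of the cross-section ratio on a 0.002-step Zeff
grid, inverted by linear interpolation — the two paths and a 0.001-step
exhaustive grid search agree to 10⁻³ (tested). Voxels whose ratio leaves
the physical range are pinned at the nearer bound, flagged, and still
propagated to SPR. RED follows in closed form; a vanishing closed-form
denominator is flagged. The default per-class pair assignment
(lung (40, 50), soft (40, 70), bone (40, 115) keV) is the frozen output of
the packaged pair optimization under default simulator conditions.

**Landry–Saito.** The ratio model is fitted in (A, B, C, m) by nonlinear
least squares with multi-start over m ∈ {3.0, 3.3, 3.6}; inside each
residual evaluation the insert EAN truth is recomputed with the trial
exponent, keeping model and truth consistent. The RED model is linear in a
reparametrization and solved exactly, then mapped back to (α, a, b).
Because inverting the ratio model voxel-wise produces unphysical `z =
Zeff^(m−1)` for a sizable fraction of noisy voxels, the per-voxel EAN→I
step is bypassed: an **isotonic (monotone piecewise-linear) regression** of
Bragg-additivity ln I on `z` over the 73 tissues provides a total, clamped
lookup — any real `z`, including negative values, maps into the fitted
range. Monotonicity is guaranteed by construction; an unconstrained spline
would not be total.

**DirectSPR-style.** α_RED is a linear least-squares fit of the RED
superposition; α_EAN is then fitted on the EAN equation using the REDs
predicted by the fitted α_RED. The printed EAN superposition requires
|α_EAN| ≫ EAN_water^3.1 to span bone (the weights on the two channels have
opposite signs); the fitted magnitude (~5·10³) is therefore expected, not
pathological. Two product internals are proprietary and carry documented
surrogates: (i) the I-value step reuses the Yang parametrization,
**rescaled so I(EAN_water) = I_w exactly**, which makes the all-zero-HU
voxel map to SPR = 1 by construction; (ii) the product's internal
spectral-domain noise suppression is represented by a fixed mild Gaussian
regularization (σ = 0.5 voxel, ~0.52× SD on white noise) of the two input
volumes inside `map_spr_direct`. Without (ii), an accurate superposition
calibration on idealized two-channel data necessarily adopts the same
Z-cancelling weights as the L-S fit and amplifies noise identically —
the observed product behaviour ("noise kept level") is a property of its
noise handling, not of the superposition algebra. ROI means on homogeneous
inserts are unaffected by the regularization. EAN_water is computed from
the water composition (≈7.45 with the 3.1 exponent) and stored in the
calibration file.

## The synthetic acquisition model

The simulator emulates the *statistical* structure of repeated DECT
acquisitions of a two-size cylindrical phantom; it does not emulate any
reconstruction chain. Voxels take the material of their center (no partial
volume); noise is zero-mean, Gaussian, spatially white, and scales as
`sqrt(dose_ref / CTDIvol)`:

* **VMI channels** share two basis-coefficient noise fields (water-like and
  bone-like; the bone basis is the packaged cortical-bone tissue): the
  noise on a VMI at energy E is `σ_w·n_w + σ_b·g_b(E)·n_b` with `g_b` the
  bone attenuation relative to water. Consequences, both tested: VMIs at
  nearby energies are correlated at >0.99, and low-keV VMIs are markedly
  noisier than mid-keV ones — the behaviour of image-space VMI synthesis
  from one basis decomposition.
* **Native-kV surrogate channels** are VMIs at fixed effective energies
  (56 / 89 keV, a low-kV / tin-filtered-high-kV-like pair) with
  **independent** per-channel noise fields, as produced by two separate
  tube/detector measurements on a dual-source scanner. Feeding the kV
  methods basis-correlated natives instead would make the L-S weighted
  difference mathematically incapable of amplifying noise above its inputs,
  contradicting the behaviour this package exists to study.
* **Noise reduction** is a strength-parameterized Gaussian smoothing
  surrogate (levels 0–3 → kernel σ of 0, 0.5, 1.0, 1.5 voxels); it
  preserves large-ROI means and strictly reduces white-noise SD.

Default magnitudes (relative-attenuation units at the reference dose,
10 mGy Body / 40 mGy Head): σ_w = 0.009, σ_b = 0.004, σ_low = 0.020,
σ_high = 0.014. They were chosen once, as the scanner-emulation
calibration of the generator, so that soft-tissue input-channel CIs at the
Body medium dose sit at a few percent and the low/high asymmetry matches a
dual-source protocol in which the filtered high-kV channel is the cleaner
one. No claim of fidelity to any specific scanner is made; what passing
tests demonstrate is the *relative* noise behaviour of the three mappers
under a controlled, physically structured noise model — not absolute noise
levels of real reconstructions, which include texture, streaks, spatial
correlation and object-dependent statistics that this model deliberately
omits.

Acquisitions are deterministic given `(base_seed, repeat_index)`; the four
noise fields are always drawn in a fixed order so a realization does not
depend on which channels were requested. Calibration acquisitions use a
dedicated seed offset and the medium dose with no noise reduction, and are
never reused for analysis.

## ROI statistics and range simulation

Insert ROIs are cylinders (d = 20 mm, h = 30 mm) at the insert centers;
statistics are the sample mean, relative SD (% of mean), adjusted
Fisher–Pearson skewness, and CI87 = 1.5 × relative SD (±1.5 SD covers
86.64% of a normal distribution), each computed per repeat and then
averaged arithmetically over the repeat set (30 by default). Constant or
zero-mean samples are flagged and report zero spread/skewness rather than
NaN.

Proton range replaces a treatment-planning dose engine with water-
equivalent path length: the SPR map is resampled (trilinearly) to a
2×2×1 mm dose grid, parallel proton tracks run along the phantom axis, and
a track's range is the depth where its cumulative trapezoidal WEPL reaches
the Bragg–Kleeman water range `R = α_BK·E^p` (α_BK = 0.0022 cm·MeV⁻ᵖ,
p = 1.77; 83.16 mm at 105 MeV), linearly interpolated between planes. The
measurement uses the 81 lattice lines nearest the ROI center (deterministic
distance-then-index ordering; the published design does not define the
lattice/circle intersection rule). Lines that exit the volume before
reaching the water range (e.g. lung inserts) are excluded with their count
reported. Absolute ranges from this proxy are not validated against a dose
engine — the quantity of interest is the noise-induced *variation* of
range, for which WEPL integration is the appropriate mechanism.

## Pair optimization

All unordered pairs on the 40–140 keV grid (5050 at 1 keV) are scored by
SPR RMSE: theoretically over the tissue library (a precomputed dense-grid
scorer makes the full enumeration take seconds) and, for robustness
analysis, on insert-ROI means of repeated noisy acquisitions. Pairs above
2% theoretical RMSE are excluded. Tissue classes follow a configurable
rule (lung: density < 0.6 g/cm³; bone: EAN(3.1) > 10; else soft — the
publications do not state their partition). Measured RMSE is pooled across
the two phantom sizes by the root of the mean of squares, ranked per
repeat (ties broken lexicographically by RMSE, then lower E1, then lower
E2), and summarized by times-ranked-first, mean ± SD RMSE and worst rank.
An optional screen (off by default) rejects pairs whose insert EAN samples
fail a D'Agostino–Pearson normality test, the documented countermeasure to
EAN distributions collapsing into discrete bound-pinned spikes.

## Problem sizes

The default experiment scale used by the tests and the acceptance script —
Body phantom at 1×1×2.5 mm with 20–50 mm axial extent for noise
statistics, single-insert reduced-field-of-view phantoms of 110 mm axial
extent for range simulation (white noise makes the statistics independent
of the field of view), 30 repeats, and 3 dose levels — was chosen as a
desk-scale design point that keeps every statistic (ROI voxel counts ~10³,
repeat counts, line counts) at the study's nominal values.

## Known limitations

* Cross sections, tissues and inserts are synthetic/nominal; absolute SPR
  accuracies are internally consistent, not traceable to measured data.
* No projection/sinogram simulation: no beam hardening, scatter, spatial
  noise correlation or reconstruction-kernel texture.
* The DirectSPR surrogate reproduces the published *pattern* (noise kept
  near input level) by an explicit regularization stand-in; no numerical
  equivalence with the commercial product is claimed.
* The Yang/I_w inconsistency at water (above) is inherited from the
  published constant set and left intact.
* Range is a WEPL proxy: no nuclear interactions, straggling, lateral
  scattering or dose deposition; absolute ranges shift accordingly.
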