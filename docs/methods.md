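# Methods

This note records the modeling assumptions, default parameter choices and
numerical decisions behind `discregen`, and what the shipped tests do and
do not establish.

## Canonical units and parameters

All internal computation uses mm / h / µM (oxygen) / mM (glucose, lactate)
/ µg/mm³ (GAG) / cells/mm³. Config files annotate every numeric leaf with
`units:` and a provenance tag (`table1`, `table2`, `measured`, `derived`,
`literature`, `calibrated`); the loader converts to canonical units and
rejects unknown keys or unit mismatches. One year is fixed at 365.25 days
(8766 h) for the half-life conversion.

Parameter provenance, by class:

* **Transcribed constants** — per-domain effective diffusivities (mm²/h)
  for glucose, oxygen and lactate (anisotropic in the AF: axial along the
  spine, radial in-plane); native and degenerated GAG contents; GAG
  synthesis rates λ₁ (6.19 / 9.08 / 8.48 pg/cell/day for rat / goat /
  human NP cells); the GAG half-life τ = 11 years; metabolically active
  cell densities (rat NP 94×10³, rat AF 93×10³, goat NP 6×10³, goat AF
  16×10³ cells/mm³); injury severities (rat puncture: 100% GAG / 75%
  cellularity loss; goat chABC: 50% / 50%).
* **Back-computed** — the dry-weight conversion factor 0.283 mg DW/mm³,
  implied jointly by the rat AF, goat NP and goat AF degenerated-content
  values (consistent to 3 significant figures); the human Grade II
  normalization reference 152.2 µg/mm³ (537.8 µg/mg DW × 0.283).
* **Literature-style defaults, clearly non-measured** — the oxygen
  Michaelis constant K_m = 3.8 µM; the glucose Michaelis constant 0.5 mM;
  oxygen solubility 10.5 µM per %O₂ (Henry's law at 37 °C); the human
  Grade III cell densities (NP 1.4×10³, AF 5×10³ cells/mm³, consistent
  with goat having ~4× the human NP density); the lactate→pH sensitivity
  0.08 pH/mM anchored at 1 mM / pH 7.35.
* **Per-cell metabolic magnitudes** — OCR/LPR defaults (rat NP 10/90,
  rat AF 12/60, goat NP 8/55, goat AF 12/60, human NP 5/50, human AF 8/55
  nmol per 10⁶ cells per h) are plausible flux-analyzer-scale values
  chosen to respect the measured orderings (human NP OCR lowest, animal
  AF OCR above the paired NP, rat NP LPR highest) and to admit
  physiological boundary oxygen during calibration. They are tagged
  `derived`, not measured.
* **Calibrated boundary values** — produced by running
  `calibrate_boundaries` against the reported healthy central
  microenvironments (rat: 2 mM glucose / pH 6.9 / 1.5% O₂; goat: 1.4 mM /
  6.9 / 2%) and baked into the configs tagged `calibrated`. Human
  boundaries are plasma-derived periannular values with CEP-attenuated NP
  interface values (`literature`); no intradiscal probe targets exist for
  human.

## Geometry

Discs are idealized as elliptic cylinders with flat endplates and an
elliptic-cylindrical NP core; one quadrant is modeled with zero-flux
symmetry planes. Default dimensions are tuned to the published anchors
rather than to unavailable imaging data: the goat NP height makes a
1×10⁶-cell dose exactly 30% of the healthy NP population (so 5.5×10⁶ is
165%), the rat NP makes 25×10³ cells 3.0%, and the human NP volume is
12× the goat NP volume (≈750× the rat NP). Dose fractions are quoted
against the healthy NP density for animals and the Grade III density for
human; with the literature human density of 1.4×10³ cells/mm³ the 1–40 M
clinical range spans ~11–430% of the Grade III population (the reported
range, ~10–383%, corresponds to a slightly larger resident population —
the ordering conclusions do not depend on this).

Rasterization labels voxels by center membership. The requested spacing is
snapped so an integer number of voxel layers spans the disc height
exactly; because every z-layer is tissue, an overshooting layer would
otherwise thicken the modeled disc by a resolution-dependent amount and
destroy mesh convergence (in-plane overshoot is harmless exterior).
Boundary tags: periannular on the outer lateral surface, NP–CEP on
top/bottom faces over the NP footprint, zero-flux over the AF footprint
(nutrition reaches the disc by exactly the two named routes).

## Transport solver

Cell-centered finite volumes, 7-point stencil, harmonic-mean interface
diffusivities (exactly conservative across the NP/AF diffusivity jump),
Dirichlet boundaries via half-cell ghosts. The nonlinear system is solved
by Picard iteration in the order glucose → lactate (source = 2× the
realized glucose sink) → pH (affine in lactate) → oxygen, with
lagged-coefficient sinks — each linearized system is a symmetric M-matrix,
so concentrations stay non-negative. Under-relaxation defaults to 0.7 for
robustness at high density contrasts; the fixed point is contractive at
all shipped parameter sets and ω = 1 converges as well. After
convergence (max relative field change < 10⁻¹⁰ by default) one final
un-relaxed pass makes the reported fields satisfy their linear systems to
round-off, so discrete flux balance (boundary influx = volumetric
consumption; production for lactate) holds to ~10⁻¹² relative.

Linear systems up to 8000 unknowns use a sparse direct solve; larger ones
use conjugate gradients with Jacobi preconditioning, warm-started from the
previous outer iterate (rtol 10⁻¹³), which keeps fine-grid solves in
seconds. Lactate boundary values are not independent inputs: they are
inferred from the boundary pH through the inverse pH coupling. The pH
map clamps at 5.0 (just above the 4.95 validity floor of the oxygen
kinetics) and flags the solve if clamping ever occurs; no shipped scenario
triggers it.

Central concentrations are interpolated to the exact disc center
(quadratic in z to mid-height, even-quadratic extrapolation across the
in-plane symmetry planes); with that probe the central values move by
< 1% when the default spacings (rat 0.1 mm, goat 0.3 mm, human 0.7 mm)
are halved. The two printed offsets in the oxygen law (4.95 numerator,
4.59 denominator) are implemented as written and kept as two distinct
named constants.

## Boundary calibration

`calibrate_boundaries` mirrors the iterative in vivo refinement procedure
with an explicit objective: least squares between predicted and measured
central glucose / oxygen / pH over repeated forward solves. One
adjustment per metabolite is applied jointly to both boundary routes
(multiplicative for glucose and oxygen, additive for pH) because a single
central measurement cannot separate the periannular from the CEP route;
bounds keep the search physiological, and hitting a bound flags the
result. On zero-noise synthetic probe data the generating boundaries are
recovered to ~1%; with 5% multiplicative probe noise over 3 discs,
recovery stays within a few percent.

## GAG regeneration

The conservation law for GAG carries a solid-matrix advection term; the
simulated scenarios involve no matrix motion, so the velocity is fixed at
zero (it remains in the data model) and the field equation reduces to
independent per-compartment linear ODEs, integrated with the exact
exponential update (machine-precision agreement with the closed form).

Resident and injected NP cells both synthesize at the measured species
λ₁, injected cells assumed fully viable, uniformly distributed and
phenotype-stable for the whole horizon — deliberately optimistic
assumptions that make predicted timelines lower bounds. Healthy baselines
instead use the homeostatic closure λ₁ = λ₂c₀/ρ₀, which the measured
rates exceed many-fold: a healthy disc in equilibrium turns GAG over
slowly, while the measured rates describe cells in regenerative, matrix-
depleted surroundings. The AF always uses the closure (its synthesis rate
was not measured). λ₂ is identical across species and grades (constant
11-year half-life); aggrecan turnover in degenerate human tissue is
plausibly faster, which would slow every predicted human recovery.

The GAG model is deliberately **not** gated by the nutrient fields: a
40 M-cell dose regenerates fastest even as it degrades the
microenvironment. Instead, scenario reports carry interpretive floor
flags (defaults: glucose < 0.5 mM, pH < 6.8, oxygen < 1% O₂ anywhere in
the NP) so a dose that stresses the niche is visible without being
rejected automatically; coupling survival to nutrition is future work.

## Flux-analyzer estimation

OCR comes from the blank-corrected linear oxygen slope on t ≥ 10 min
(the stated plateau rule), converted at 1.3 µM/mmHg and scaled by the
2.3 µL microchamber volume; both constants are configurable. LPR maps the
pH series to lactate through an affine standard curve and fits the
maximal trailing linear window, found by trimming leading points that sit
> 3 studentized residuals off the tail fit — pure-noise linear traces
keep every point, curved transients are trimmed. λ₁ is total accumulated
GAG / cells / days. Outlier screening approximates the named commercial
procedure as a robust location/scale (median/MAD) test with
Benjamini–Hochberg control at Q = 1%, passing through (with a warning)
below 8 replicates. An optional live-fraction correction is off by
default since viability was not quantified in the normalization.

## Synthetic data

Generators embed known truths and a seed in every artifact. Instrument
noise is additive Gaussian (oxygen 0.2 mmHg, pH 0.002 — modern
flux-analyzer scale); biochemical assays and probes carry multiplicative
noise (CV 10% and 5%). The oxygen pre-plateau transient is an exponential
approach over the first ~10 min so the cutoff rule is exercised. The
default standard curve spans 0–2 mM lactate at −0.6 pH/mM (weakly
buffered assay medium). At these defaults, 200-trace recovery of OCR and
LPR has median relative error ~3%. What passing recovery tests show is
that the estimators invert the generators' noise model — not that they
would be unbiased against real instrument drift, well-to-well coupling or
plateau misidentification on hardware data.

## Problem sizes

Default grids run 3–7×10³ tissue voxels per species (seconds per solve);
mesh-convergence checks use one uniform refinement (up to ~10⁵ voxels via
the CG path). Dose sweeps reuse one rasterized grid. The full test suite
solves each species once at default resolution plus a handful of coarse
calibration grids.

## Known limitations

* Geometry is idealized (no lordotic wedge, bulge or endplate curvature);
  dimensions are anchor-tuned, not segmented from imaging.
* The CEP is not meshed; its transport resistance is folded into the
  NP-interface boundary values, so those values are effective, not
  directly measurable quantities.
* No Pasteur effect (LPR independent of local oxygen), no
  nutrition-dependent cell death, no collagen regeneration, no
  biomechanics, no transient nutrient dynamics.
* The lactate→pH coupling is a calibrated affine stand-in for the
  buffering chemistry of disc tissue.
* OCR/LPR magnitudes are defaults in the absence of printed numbers;
  conclusions that depend on their absolute scale (rather than the
  between-species orderings) should be re-run with measured values.
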