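# Methods

## Spectral model and preprocessing

A spectrum is a sampled absorbance curve on a strictly increasing wavenumber
grid; construction sorts the points, so every downstream result is invariant
to input order. Absorbance is treated as unitless: no ATR penetration-depth
correction is applied, which is acceptable because every quantity reported is
a ratio (area fractions, width indices, scaled subtractions).

Preprocessing steps and their parameters:

* **Reference subtraction.** Water vapor is removed by choosing the scale k
  that minimizes the roughness (sum of squared second differences) of
  s − k·ref over the signal-free 1700–1900 cm⁻¹ window: the vapor comb is the
  only sharp structure there, so the smooth sample background does not bias
  k. Liquid water is removed by least-squares amplitude matching on the
  2000–2300 cm⁻¹ association band, where the protein does not absorb. The
  recovered scale is returned so the correction is auditable. A residual
  water error appears as a broad baseline incurvature, but second
  differentiation suppresses it below 1 % of the narrow-band amplitude
  (derivative amplitude ∝ area/FWHM³; FWHM 120 versus 10–16 cm⁻¹).
* **Resampling.** Uniform grid from ceil(min) to floor(max), default step
  1 cm⁻¹ (the instrument grid is 4 cm⁻¹; the finer working grid stabilizes
  derivative filtering). Interpolation uses a degree-7 B-spline: on a
  band-shaped curve sampled at 4 cm⁻¹ the refinement error stays below
  10⁻³ of peak height for FWHM ≥ 12 cm⁻¹, which linear and cubic
  interpolation do not achieve.
* **Second derivative.** Savitzky–Golay, default window 13 points, polynomial
  order 3, on the uniform grid. Edge samples (window//2 per side) are trimmed
  rather than extrapolated; the Amide I fit region (1600–1700 cm⁻¹) is padded
  by the generator range (1580–1720 cm⁻¹) so trimming never touches it.

## Amide I band fitting

The fit target is the inverted (sign-flipped) second derivative, floor-clipped
at zero. Components are Gaussian absorbance bands with parameters (center,
FWHM, area); the model curve is obtained by pushing the band sum through
exactly the same operator that produced the data — Savitzky–Golay second
derivative with the same window and order, inversion, clipping — plus a
co-fitted constant offset that guards against any residual baseline. This
operator-consistent construction is the load-bearing numerical choice: the
central clipped lobe of one band's second derivative is partially cancelled
by the negative wings of its neighbours before clipping, so fitting free
Gaussian shapes directly to the clipped contour systematically misattributes
area between the closely spaced β components (in the worst case the
1639 cm⁻¹ lobe almost vanishes). With the operator-consistent model the
noiseless fit recovers the generating band parameters exactly (residual rms
at machine precision).

Constraints follow the fitting protocol of the study system: centers are
bounded to init ± 4 cm⁻¹; areas are non-negative by bounded optimization (not
post-hoc clipping); with `fix_fwhm` the widths are frozen and returned
bit-exactly. The complexed-state ("gel") protocol reuses the native fit as
initialization, keeps all bandwidths fixed, and frees only the β-component
centers — this is how the 1639 cm⁻¹ band is allowed to migrate to ~1635 cm⁻¹
while the comparison between states stays well-posed. The open question of
whether the native 1639 and gel 1635 bands are one shifting component or two
distinct ones is resolved here as a shifting component, which the protocol
encodes directly.

Assignment table (center → class): β for 1615–1645 cm⁻¹, α for
1645–1665 cm⁻¹, turns for 1665–1700 cm⁻¹. Side-chain absorbance
(1610–1630 cm⁻¹) is not given its own component in the five-component
configuration; an optional six-component mode assigns a `side` class that is
excluded from the fractions. Fractions are computed from the fitted
(absorbance-domain) component areas; whether to integrate in the derivative
or absorbance domain is an open choice in the field, and the operator-
consistent parameterization makes the absorbance-domain areas directly
available, so those are used.

Tolerances observed in validation: noiseless five-band recovery is exact to
< 0.01 percentage points; with white noise at 2 % of the second-derivative
peak amplitude and the fixed-bandwidth protocol, fractions stay within 1
percentage point over 50 seeded replicates. Noise injected into the
*absorbance* instead is amplified roughly 50-fold by differentiation at this
grid and window, and free-width fits on such data can diverge by several
points — which is precisely why the constant-bandwidth protocol exists.

## Carrageenan chain state

"Helix quality" has no standard numeric definition; this package
operationalizes it as the mean FWHM of the resolved fingerprint components.
The classifier locates second-derivative minima in 1000–1100 cm⁻¹ (peak
prominence ≥ 10 % of the region maximum on the normalized contour, so the
call is invariant to absorbance scaling), then jointly fits one Gaussian band
per detected component through the same derivative operator (window 21 here:
the broader smoothing buys noise robustness, and operator consistency removes
the width bias smoothing would otherwise introduce — a single-lobe Gaussian
fit overestimates a 10 cm⁻¹ band by ~3 cm⁻¹). Width initialization comes from
the measured lobe half-widths. The helix/coil threshold is 18 cm⁻¹, midway
between the synthetic helix (10 cm⁻¹) and coil (25 cm⁻¹) presets. Validation:
noiseless width recovery is exact across 8–30 cm⁻¹, the index is monotone in
the generator width at 1 % noise, and 40 seeded replicates at 2 % noise
classify 20/20 + 20/20.

Protein contamination is removed before classification by scaling the protein
reference to match the mixture's Amide II integral (1500–1580 cm⁻¹, where the
polysaccharide does not absorb) and subtracting. The sulfate-stretch region
(1200–1300 cm⁻¹) is carried through I/O but not used for classification.

## Stoichiometry

Supernatant protein is quantified by Beer–Lambert at 280 nm
(ε = 30.4 mM⁻¹cm⁻¹ for GAPDH); the sedimented fraction is 1 − c_sup/c₀,
clipped to [0, 1], with a 5 % mass-balance tolerance above which the series
is rejected as inconsistent. The breakpoint model is a single hinge
f(q) = min(q/q\*, 1) — linear uptake then saturation; q\* is found by dense
scan plus bounded refinement of the 1-D least-squares objective. Degenerate
series (everything sedimented) report q\* = min(q) flagged as a lower bound;
a breakpoint outside the observed grid is flagged extrapolated. No
uncertainty beyond the least-squares objective is reported.

The disaccharides-per-tetramer count uses default molar masses of 144,000
g/mol for the tetramer (4 × ~36 kDa chains) and 386 g/mol for the
kappa-carrageenan disaccharide repeat (free-acid form); both are arguments,
and with q\* = 0.2 they give round(74.6) = 75. The FTIR cross-check of
supernatant composition (protein bands below q\*, polysaccharide bands above)
is not computed from spectra; it enters only as a user-supplied consistency
observation.

## Docking post-processing

The positional criterion for clustering is the Euclidean distance between
ligand centroids, not an all-atom RMSD: the grouping is meant to capture
poses at one surface locus irrespective of fragment orientation, and an
orientation-sensitive RMSD would contradict that. Clustering is energy-ranked
leader clustering (the docking community's convention): poses are visited by
ascending energy, ties broken by input index, and each joins the first leader
within 15 Å or founds a new cluster. Populations are conserved and the result
is input-order invariant; because the leader is a random member of a spatial
cloud, an outlying pose can fall beyond the cutoff and found a tiny satellite
cluster — such satellites are below the population floor of the true-positive
rule and are discarded.

True positives are clusters with population ≥ 5 % of all poses *and* best
energy within 1 kcal/mol of the global minimum (both configurable): a
quantitative version of judging the population-versus-energy scatter by eye.
Contact mapping uses a 4.0 Å heavy-atom cutoff (hydrogens ignored); epitope
comparison is Jaccard overlap of residue numbers against the built-in GAPDH
sets (NAD-groove S-loop, OP helix, OP S-loop, OR edge strands). Binding
energies are normalized per disaccharide in direct protein contact (e.g. 3
for a hexamer fragment, 10 for a double-helical fragment). The absolute
docking energies of the study system require the docking engine, biased
grids and MD-derived water clusters, all out of scope here; only the
normalization arithmetic and the geometric post-processing are implemented,
validated against brute-force distance oracles. The sign of the reported
double-helix value for one contact is ambiguous in the literature source and
is asserted nowhere.

## Synthetic data

Generators are pure functions of (parameters, seed) and define the study
conditions rather than tunable fixtures. The native protein preset encodes
bands (center/FWHM/area %) (1624, 14, 22.5) and (1639, 16, 22.5) β,
(1655, 16, 34) α, (1678, 12, 12) and (1691, 10, 9) turns — totals 45/34/21;
the gel preset (1624, 14, 10), (1635, 16, 38), (1655, 16, 30), (1678, 12,
13), (1691, 10, 9) — α = 30. Turn centers sit inside the 1674–1696 cm⁻¹ turn
window; the β/turn splits and all widths are generator choices of plausible
protein bandwidths. Backgrounds: broad liquid-water band (1640 cm⁻¹, FWHM
120) with an association band (2130 cm⁻¹) at 25 % relative amplitude, water
peak 2× the Amide I maximum; vapor comb of 30 lines (FWHM 2 cm⁻¹) at fixed
pseudo-random positions in 1300–1900 cm⁻¹, 5 % of the Amide I peak. When a
background is requested the grid extends to 1300–2400 cm⁻¹ so both
reference-scaling windows are covered; an Amide II band (1548 cm⁻¹, FWHM 45,
half the Amide I area — a typical intensity ratio) is added whenever the grid
reaches below 1500 cm⁻¹ so protein subtraction can be exercised. Spectral
noise is additive white scaled to peak amplitude; no 1/f or instrument
line-shape model is attempted. Carrageenan fingerprint components sit at
1010/1040/1070 cm⁻¹ (chosen inside the 1000–1100 cm⁻¹ window; no canonical
centers exist) with relative areas 1.0/1.5/1.2.

The mixing series applies the hinge model with multiplicative noise under the
study's Beer–Lambert parameters (c₀ = 5 mg/mL, ε = 30.4, 1 cm path, mass-ratio
grid 0.1–1.0). Pose clouds are isotropic 3-D Gaussians (σ = 3 Å) of
single-atom poses with per-cluster normal energies; centre spacings below 4σ
trigger a warning because the generator truth becomes ambiguous.

What passing tests do and do not show: the generators share the pipeline's
band-shape family (Gaussian), so noiseless round trips are exact by
construction and validate the estimators, not the band-shape assumption.
Real spectra have Voigt-like shapes, correlated baselines, and imperfect
reference spectra; the subtraction and derivative stages address those only
to the extent the synthetic backgrounds mimic them.

## Problem sizes and determinism

Default analyses run on 141-point Amide I grids, 901-point carrageenan grids,
10-ratio mixing series and 100–200-pose clouds; the full test suite and the
acceptance script each complete in well under a minute on one core. All
randomness flows through explicit integer seeds.

## Known limitations

* Band fitting assumes Gaussian component shapes; Voigt or Lorentzian wings
  are not modelled.
* The helix-quality threshold (18 cm⁻¹) is calibrated on the synthetic
  presets, not on measured gel spectra.
* Leader clustering is order-deterministic but cutoff-sharp: poses near the
  boundary can found satellite clusters (handled by the population floor).
* The hinge model has a single breakpoint; cooperative or multi-step uptake
  would need a different model.
* JCAMP-DX support covers AFFN `(X++(Y..Y))` and `(XY..XY)` tables only
  (no compressed DIF/DUP forms).
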