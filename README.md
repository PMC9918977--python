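# carragel

Analysis toolkit for studying how a multimeric protein rearranges when it is
immobilized in a kappa-carrageenan gel, built around the GAPDH-carrageenan
system: glyceraldehyde-3-phosphate dehydrogenase, a homotetramer whose
intersubunit contacts loosen on complexation with the sulfated seaweed
polysaccharide. It is written for spectroscopists and modellers who need the
full quantitative chain from raw ATR-FTIR traces and docking-pose sets to
secondary-structure fractions, chain-state calls, complex stoichiometry and
binding epitopes — with seeded synthetic generators so every stage is testable
without instrument data.

## What it computes

**Amide I deconvolution.** The Amide I band (1600–1700 cm⁻¹) is a sum of
Gaussian components whose centers report secondary structure (β-structure
1615–1645, α-helix 1645–1665, β-turns 1665–1700 cm⁻¹). The pipeline subtracts
water-vapor and liquid-water references, resamples to a 1 cm⁻¹ grid, takes a
Savitzky–Golay second derivative D²A(ν̃) (broad backgrounds drop out because
derivative amplitude scales as area/FWHM³), and fits the inverted, clipped
contour with five Gaussian bands

&nbsp;&nbsp;A(ν̃) = Σᵢ (aᵢ / σᵢ√2π) · exp(−(ν̃ − ν̃ᵢ)² / 2σᵢ²),

propagated through the same derivative operator as the data. Fractions are
area percentages by assignment, with the whole Amide I area as 100 %.

**Chain-state classification.** Helical carrageenan shows sharp fingerprint
components (1000–1100 cm⁻¹); the coil shows broad ones at the same positions.
The helix-quality index is the mean fitted component FWHM; below 18 cm⁻¹ the
chain is called helix.

**Stoichiometry.** Sedimented protein fraction versus polysaccharide/protein
mass ratio q follows a hinge, f(q) = min(q/q\*, 1); least squares recovers the
stoichiometric ratio q\* and round(q\* · M_tetramer / M_disaccharide) gives the
disaccharide repeats bound per tetramer.

**Docking post-processing.** Energy-ranked leader clustering of pose centroids
(15 Å cutoff), population-versus-energy true-positive selection, binding-energy
normalization per protein-contacting disaccharide, and heavy-atom contact /
epitope mapping against the GAPDH S-loop, OP-helix and OR-edge residue sets.

## Worked example

```python
from carragel import amide1, synthetic

native = synthetic.make_protein_spectrum("native")   # noiseless preset
fit = amide1.deconvolve(native)
print(fit.fractions)
# SecondaryStructureFractions(beta=45.0, alpha=34.0, turn=21.0)

gel = synthetic.make_protein_spectrum("gel")
refit = amide1.gel_refit(gel, fit)                   # fixed bandwidths
print(round(refit.fractions.alpha, 1))               # 30.0
delta = amide1.compare_states(fit, refit)
print(round(delta.delta_near(1624), 1), round(delta.delta_near(1637), 1))
# -12.5 15.5
```

Reading: 45 % β / 34 % α / 21 % turns in solution; in the gel the α content
stays at 30 % while 12.5 area-% leaves the 1624 cm⁻¹ β band and the second β
band, shifted to 1635 cm⁻¹, gains 15.5 — the infrared signature of partial
tetramer dissociation rather than unfolding.

The numbered drivers under `analysis/` run the whole study end to end
(simulate inputs, deconvolve both states, classify the polysaccharide,
fit the stoichiometry, post-process the pose cloud) and write their tables
under `results/`. There is also a thin CLI: `carragel deconvolve`,
`carragel conformation`, `carragel stoichiometry`, `carragel simulate ...`.

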