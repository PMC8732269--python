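# cellpolar

Quantification of **organelle spatial distribution in single cells** from
fluorescence microscopy. Given a summed-intensity projection of a confocal
z-stack and binary masks for the nucleus, the cell outline and neighboring
cells, `cellpolar` resamples the fluorescence into polar coordinates about
the nucleus center, normalizes the radial axis per angle so cells of
different size and shape become commensurable, and summarizes each cell
with two statistics that discriminate the classic positioning phenotypes of
the endoplasmic reticulum and other organelles: *dispersed* (signal pushed
toward the cell periphery) and *clustered* (signal collapsed to one side of
the nucleus).

It is aimed at cell biologists quantifying organelle positioning
(ER, lysosomes, mitochondria, ...) per cell across genetic or drug
perturbation groups, and ships a synthetic phantom generator with analytic
ground truth so every stage of the pipeline can be validated end to end.

## The method

1. **Polar sweep.** From the nucleus center a radius is drawn out past the
   furthest point of the cell and swept through 360° in 0.1° steps, taking a
   bilinearly interpolated line profile at each angle. Jacobian area
   weights w = r·Δθ·Δr correct for the square shape of the pixels, so
   weighted sums over the (r, θ) map estimate Cartesian integrals
   (intensity is conserved through the transform).
2. **Per-angle normalization.** At each angle the radii of the nuclear
   envelope, r_ne(θ), and of the cell edge, r_edge(θ), are found from the
   masks, and the radial axis is rescaled to a normalized coordinate u:
   cytoplasm from 0 (nuclear envelope) to 100 (cell edge), nucleoplasm
   stretched over −25..0 as a control band.
3. **Spatial probability mass function.** The weighted intensities are
   normalized to sum to one: p(θᵢ, uₖ) = w·F / Σ w·F, treating the image
   as a discrete spatial distribution.
4. **Metrics.** Per cell:
   - **MDR** (mean distribution radius): MDR = Σ p·ρ with ρ = u
     (normalized, %) or the raw radius in μm. Higher MDR = more
     peripheral signal.
   - **Asymmetry**: the circular mean resultant length of the angular
     marginal q(θ) = Σₖ p(θ, uₖ), i.e. |Σ q·e^{iθ}| ∈ [0, 1]; 0 for
     angularly uniform signal, 1 when all mass sits at one angle;
     rotation-invariant, with a companion mean angle.
5. **Group statistics.** Per-cell metrics are compared across groups with
   the unpaired two-sided t-test, Mann–Whitney, Kruskal–Wallis, or one-way
   ANOVA followed by Dunnett's test against a reference group; summaries
   are reported as mean ± s.d.

The synthetic module generates star-convex cell phantoms whose organelle
density is specified directly in (u, θ) — a radial mixture
(perinuclear / peripheral / uniform) times a von Mises angular factor —
so normalized MDR and asymmetry have geometry-independent ground truth
evaluated by an independent dense quadrature oracle, with Poisson + read
noise rendering for realism.

## Worked example

Simulate a "clustered" phantom panel and quantify one cell:

```
$ cellpolar simulate clustered --n-cells 3 --seed 42 --out demo
wrote 3 cells; manifest at demo/manifest.csv

$ cellpolar quantify --image demo/clustered_000.tif \
    --nucleus-mask demo/clustered_000_nucleus.tif \
    --cell-mask demo/clustered_000_cell.tif --pixel-size 0.2
cell_id: clustered_000
mdr_normalized_pct: 25.430
mdr_raw_um: 6.3029
asymmetry: 0.7972
mean_angle_rad: 1.5658
domain: full
```

The cell's fluorescence sits on average 25.4% of the way from the nuclear
envelope to the cell edge (6.30 μm from the nucleus center) — a
perinuclear profile — and is strongly one-sided (asymmetry 0.80, toward
the angle 1.57 rad). The generator's own ground truth for this cell
(`demo/ground_truth.csv`: MDR 25.17, asymmetry 0.80) agrees to ~1%,
despite shot noise.

Batch a whole panel and compare groups:

```
cellpolar batch --manifest demo/manifest.csv --out metrics.csv --pixel-size 0.2
cellpolar compare --metrics metrics.csv --metric mdr_normalized \
    --test anova_dunnett --reference wildtype --out report/
```

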