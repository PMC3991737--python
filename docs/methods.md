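# Methods

This note documents the models, conventions, and numerical choices behind
`rootscan`, and what the synthetic tests do and do not establish about real
scanner data.

## Imaging

The restoration chain assumes white-ish roots on darker, wet germination
paper, scanned in colour. The red channel carries the best root/paper
contrast and is used alone. Denoising is a median filter (radius 1 px by
default; removes condensation specks) followed by a Gaussian blur (σ = 1 px;
suppresses paper grain). Background flattening subtracts the local mean in a
square window of half-width 25 px (at 300 dpi ≈ 4× the largest root
diameter) and re-centres the image at mid-grey 128: gradients on scales
larger than the window (moisture, lamp falloff) vanish, while structures
thinner than the window — the roots — survive. The window must exceed the
root diameter; 25 px is the default, scaled by dpi/300 in the pipeline
configuration if needed.

**Thresholding** is moment-preserving: with normalized histogram moments
m₁, m₂, m₃, the two representative levels z₀ < z₁ and the mass fraction p₀
solve the three moment-preservation equations (z₀, z₁ are the roots of
z² + c₁z + c₀ = 0 with c₀ = (m₁m₃ − m₂²)/(m₂ − m₁²),
c₁ = (m₁m₂ − m₃)/(m₂ − m₁²), and p₀ = (z₁ − m₁)/(z₁ − z₀)). The returned
threshold is the grey level whose cumulative histogram fraction is nearest
p₀, ties broken toward the lower level; it is deterministic given the
histogram and matches an exhaustive 256-candidate scan that minimizes the
third-moment mismatch (tested on 50 random images per run). A constant
image has no threshold and raises.

**Polarity**: after flattening, roots are the brighter class; `--invert`
flips the mask exactly for dark-root setups.

**Cleanup** keeps the 8-connected component at (or nearest, within 300 px)
the seed point — top-centre by default, where the seedling is placed — plus
any component of at least `min_area` px² within a one-pixel gap of it. The
seed component itself must be root-sized (≥ `min_area`); otherwise the
nearest large component is used, so a noise speck over the seed pixel
cannot capture the filter. Cleanup never adds foreground.

**Measurements.** Lengths use the 1-px skeleton with axial steps of 1 px
and diagonal steps of √2, each adjacency counted once and staircase
diagonals suppressed when the two pixels share an axial neighbour. The
perimeter traces each component's outer boundary through the Moore
neighbourhood with the same step weights; a single pixel has perimeter 0
under this convention, and a digitized disc of radius 50 px comes out ~5%
above 2πr — the known overestimate of unsmoothed 8-connected chain codes,
accepted here for fidelity to the step-counting definition. Hull area is
the convex hull of pixel centres. Conversion is 2.54/dpi cm per pixel.

## Architecture

The mask is thinned and partitioned into a graph: skeleton pixels of degree
≠ 2 are nodes, maximal degree-2 chains are edges carrying their polyline
and per-point Euclidean-distance-transform radii. Thinning artefacts are
handled in three steps: junction pixels that are 8-adjacent are contracted
into one node (a thick branch point thins to a small cluster); tip-ended
spurs shorter than 10 px are pruned, *except* at the topmost tip, which is
the seed end of the primary and always real; remaining degree-2 nodes are
merged away.

The **primary root** is the path from the node nearest the seed point to
the tip maximizing (path length − 0.2 × cumulative horizontal travel) — a
gravitropic prior that prefers the long downward axis over long sideways
laterals. **Laterals** are one per non-primary branch at each primary
junction: the path to the farthest reachable tip in that subtree, never
reusing an edge already claimed by an earlier lateral (crossing laterals
create cycles in the graph; edge-claiming keeps total lateral length
conservative and extraction polynomial). Laterals shorter than 0.05 cm are
discarded as unresolvable.

**Diameter** is 2·median(radius) − 1 px, converted to mm. The −1 px
corrects the distance transform's half-pixel-per-side overshoot (it
measures to the centre of the nearest background pixel). The median is
taken over the interior 70% of each edge, because the transform inflates at
junctions and deflates at tips. **Insertion angle** is the unsigned angle
between two secants: the primary's over ±20 points around the junction and
the lateral's over its first 20 points. Short secants quantize direction
too coarsely (a 10 px window shows a +2–3° bias on rendered scenes); 20 px
brings the mean-angle error under ~1.5° while remaining local (1.7 mm at
300 dpi). Branching density divides lateral count by the whole primary
length (matching the per-cm units of the field's tables), not by the
branched zone only.

RSML 1.0 files store the scene→plant→root hierarchy with polylines,
point-level diameters, and scalar annotations; write→read round-trips
exactly up to float formatting.

## Growth dynamics

Root elongation is sigmoidal: L(t) = Ø₁/(1 + exp(−Ø₃(t − Ø₂))) with
asymptote Ø₁ (cm), inflection Ø₂ (days after sowing), and rate Ø₃ (day⁻¹).
This parameterization is adopted because published rate values of
0.2–0.3 are dimensionally sensible only as day⁻¹ over a 15-day experiment.
The retained model gives each genotype its own asymptote with shared Ø₂ and
Ø₃ — genotypes follow the same growth pattern and differ in final size —
fitted as fixed per-genotype parameters by joint nonlinear least squares
(a cell-means approximation to a random-asymptote mixed model, which is
what per-genotype asymptote tables report). Two alternatives (all
parameters shared; all per-genotype) are fitted as well and ranked by
Gaussian AIC = n·log(RSS/n) + 2k. The optimizer multi-starts from the fixed
grid Ø₁ ∈ {max y, 2·max y} × Ø₂ ∈ {25, 50, 75}% of the time range × Ø₃ ∈
{0.1, 0.3, 1.0} and keeps the best residual; zero-noise recovery is exact
to 1e−6 relative, and fits are invariant to plant order and equivariant to
time shifts.

A lateral's elongation rate is its length divided by time since emergence
(emergence measured from transfer to the platform, at 3 days after sowing).
Rates follow rate(tₑ) = (b_i1 + β₁) + β₂tₑ + β₃tₑ², genotype-specific
intercept, shared β₂, β₃, by ordinary least squares with tₑ centred before
solving (collinearity) and coefficients mapped back to the raw scale.

## Variance statistics

Replicate number: two populations share the trait's CV; with R replicates
each, the two-sided (1−α) confidence intervals of two means differing by δ%
separate when R ≥ (2·z₍α/2₎·CV/δ)². Defaults δ = 50, α = 0.05 give the
constant (2·1.959964)² = 15.366. z rather than t quantiles: the
reconstruction of the reference screen's printed replicate column works
with z and would require iteration with t.

Variance components: the model is y = μ + Σₖ uₖ + ε with each random
effect uₖ ~ N(0, σₖ²) indexed by one factor or interaction.
The `single` design uses run and scanner; the `multi` design uses genotype,
genotype×run, genotype×scanner, genotype×run×scanner (the decomposition
behind heritability). Scanner is a physical device reused across runs
(crossed with run, labels shared) — treating it as nested would make
genotype×scanner indistinguishable from genotype×run×scanner; the estimator
detects and rejects designs where two terms induce the same grouping of
observations. Estimation is REML on the standardized trait: V(θ) =
Σₖ θₖ ZₖZₖᵀ + θ_res·I, deviance log|V| + log(1ᵀV⁻¹1) + rᵀV⁻¹r minimized by
L-BFGS-B with variances bounded at zero (negative estimates truncate at the
boundary, matching printed 0.00 entries) from three fixed starts. On
balanced one-way designs this matches the closed-form ANOVA estimator to
1e−7 and, on nested designs, statsmodels' MixedLM to 0.02 SD units (both
verified in the test suite).

**Source-of-variation percentages are SD shares**, each effect's SD divided
by the sum of all effect SDs — not variance shares. This is statistically
unconventional but is the only convention consistent with the printed
tables of the screens this package mirrors (verified on multiple rows);
heritability, by contrast, is the variance ratio H² = σ²g/(σ²g + σ²gr +
σ²gs + σ²grs + σ²). CV is 100·SD(n−1)/mean.

## Synthetic data

The generator draws what the platform grows: per plant, a logistic primary
(Ø₂ = 8.82 d, Ø₃ = 0.211 d⁻¹; asymptote mean 13.7 cm so the reference
plant reaches ~12 cm by day 18, with genotype and plant-level spread)
descending with a gentle heading wiggle (±5°, 6 cm wavelength); laterals
initiate as a Poisson process of 2.61 cm⁻¹ along the growing primary,
emerge 2 days after the tip passes, and elongate at a constant per-root
rate from the quadratic model (intercept 0.26 cm d⁻¹, β₂ = 0.02,
β₃ = −0.004, small noise); insertion angles ~N(77.3°, 4.5°); diameters
0.49/0.38 mm (primary/lateral). All defaults are the reference screen's
published means. Draws are ordered deterministically (plant parameters,
then laterals in emergence order) from a single seeded generator.

Rendering stamps each root's centerline onto the canvas and takes one
distance transform per rounded stroke radius: the truth mask is the set of
pixels within the radius; the image adds an anti-aliased coverage ramp,
then background level, a smooth moisture gradient, correlated paper
texture, bright condensation specks, and sensor noise — noise affects the
image only, never the truth mask. With all noise off, thresholding the
render reproduces the truth mask exactly. The colour render keeps full root
contrast in the red channel and ~40% of it in green/blue.

Population simulation draws the additive random-effects model directly,
with the platform's layout: the same scanner bank in every run, one
genotype per scanner sheet (two plants), assignment re-randomized each run.
Both choices are identifiability requirements — same-genotype plant pairs
separate the three-way interaction from the residual, and re-randomized
assignment makes genotype×scanner pairs recur across runs.

## What passing tests show — and what they don't

The renders emulate the dominant noise sources of scanner images (gradient,
grain, specks) but not root hairs, root overlap in dense mats, translucent
young tissue, condensation sheets, or paper-fibre pseudo-roots. Recovery
results on renders therefore bound algorithmic error, not biological
measurement error. Known biases, quantified on renders: segmentation after
blur widens strokes ~1.5 px, inflating diameters measured on *noisy*
renders by ~0.1 mm (diameters on clean masks are accurate to ~0.02 mm);
closely spaced or crossing laterals can merge at a junction, undercounting
laterals by a few percent at the default 2.6 cm⁻¹ density; the Moore-trace
perimeter overestimates smooth curves by ~5%. The original macro pipeline
this follows was itself reported to underestimate total root length
against interactive tracing (R² = 0.77); no correction factor is published,
and none is applied.

Small variance components are weakly identified: in the multi-genotype
design sized like the reference screen (~200 plants), a genotype×scanner SD
of 1.38 against a residual of 10.1 is driven to the zero boundary in most
replicates. Tests therefore demand 25% median recovery only for the
well-identified components (genotype, genotype×run, residual) and bound the
small ones absolutely. Printed H² values of the reference multi-genotype
screen are not reproducible from its printed SDs under the stated
definition (they presumably involve unstated replicate counts) and are not
used as checks.

## Problem sizes

Test scenes are single plants at 10×14 cm, 300 dpi (≈1650×1180 px), day 15;
the CLI demo uses 6–9 cm canvases at 150 dpi. Simulation-based checks use
20 seeded replicates (growth-fit recovery, variance components) or 50 (AIC
model selection, threshold oracle); the Monte-Carlo bias check for the
residual SD uses 200 replicates of a reduced 3-run × 4-scanner design.
These sizes were chosen to keep every check's Monte-Carlo error well inside
its tolerance.
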