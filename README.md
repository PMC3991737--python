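# rootscan

Root phenotyping for pouch-and-wick scanner platforms: plants grow on
vertical germination paper in front of flatbed scanners, which image the
root system daily without disturbing it. `rootscan` turns those time-lapse
scans into quantitative root-system-architecture traits and fits the
statistical models such a screen needs — who it is for: anyone running (or
simulating) a paper-based root screen who wants segmentation, architecture
traits, growth curves, and replication/heritability statistics in one
scriptable package.

## What it computes

**Imaging.** Red-channel extraction, median + Gaussian denoising,
local-mean background flattening, moment-preserving (Tsai) thresholding —
the threshold *t* and two representative grey levels are chosen so the
binary image preserves the first three moments of the grey histogram — then
connected-component cleanup and global traits: total root length (1-px
skeleton, axial steps 1 px, diagonal steps √2), projected area, traced
boundary perimeter, and convex-hull area, all in cm via the scan dpi.

**Architecture.** A skeleton graph (junction/tip nodes, centerline edges
with per-point radii from the Euclidean distance transform) yields the
primary root (longest gravitropically-plausible path from the seed point),
first-order laterals, diameters, branching density (laterals per cm of
primary), and insertion angles. Systems serialize to RSML 1.0.

**Dynamics.** Primary and total root length follow a logistic curve
L(t) = Ø₁ / (1 + e^(−Ø₃(t−Ø₂))) with a genotype-specific asymptote Ø₁ and
shared inflection Ø₂ (days after sowing) and rate Ø₃ (day⁻¹); alternative
parameter structures are ranked by AIC. Lateral elongation rate (length
over time since emergence) is modelled as a quadratic in emergence day with
a genotype-specific intercept.

**Variance statistics.** Coefficients of variation; the replicate count
needed to separate two means differing by δ% with non-overlapping two-sided
(1−α) confidence intervals, R = (2·z₍α/2₎·CV/δ)²; REML variance components
for the run/scanner and genotype × environment designs;
source-of-variation percentages (shares of the effect *standard
deviations* — the reporting convention of the screens this package
mirrors); and broad-sense heritability H² = σ²g/σ²p.

**Synthesis.** A generator that draws whole plants (logistic primary
growth, Poisson lateral initiation along the growing primary,
emergence-day-dependent elongation rates, configurable angles and
diameters), renders them as scanner-style images with moisture gradients,
paper texture, and condensation specks — alongside the exact truth mask —
and simulates trait populations with known variance components.

## Worked example

```bash
# render 2 synthetic plants at 4 days each, with ground truth
rootscan simulate --seed 7 --n-plants 2 --das 6,10,14,18 --out demo/

# segment one scan and measure global traits
rootscan segment demo/plant000_18.png --dpi 300 --out demo/seg
# -> total root length 66.45 cm, area 3.708 cm2, perimeter 128.36 cm, hull 49.04 cm2

# architecture traits from the mask
rootscan traits demo/seg/plant000_18_mask.png --rsml demo/p0.rsml --csv demo/p0.csv
# -> primary 12.33 cm x 0.59 mm; 22 laterals (1.78 per cm); total 63.40 cm

# full pipeline: segment every image, fit growth curves, decompose variance
rootscan run demo/ demo/metadata.csv --out demo/results
```

The numbers are what the commands print for seed 7. The generator's ground
truth for this plant at 18 days after sowing (`demo/truth_traits.csv`) is
65.5 cm of total root on a 12.0 cm primary with 29 laterals: skeleton
length lands within ~1.5% of truth, while on a default-noise scan the
architecture layer merges a few adjacent junctions (22 counted) and the
measured diameter carries the segmentation's ~0.1 mm blur widening —
see `docs/methods.md` for both effects.

Library use mirrors the CLI: `rootscan.segment_pipeline`,
`rootscan.extract_root_system`, `rootscan.fit_logistic`,
`rootscan.fit_variance_components`, `rootscan.simulate_architecture`, etc.

## Layout

- `src/rootscan/imaging.py` — restoration, Tsai threshold, cleanup, global traits
- `src/rootscan/architecture.py`, `rsml.py` — skeleton graph, local traits, RSML I/O
- `src/rootscan/dynamics.py` — trajectories, logistic and lateral-rate fits
- `src/rootscan/varstats.py` — CV, replicate number, REML components, H²
- `src/rootscan/synthesis.py` — ground-truth generator and renderer
- `src/rootscan/refdata.py` — published screen summaries used as inputs
- `src/rootscan/pipeline.py`, `cli.py`, `io.py` — end-to-end pipeline and CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
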