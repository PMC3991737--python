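"""Published summary statistics of the pouch-and-wick *Brassica rapa* screens.

These numbers are inputs, not outputs: the trait means, coefficients of
variation, and effect standard deviations reported for (a) the
single-genotype screen of cv. R-o-18 (72 seedlings, five runs x eight
scanners x two plants, assayed at 18 DAS) and (b) the multi-genotype screen
of the two BraIRRI parents (IMB211, R500) plus 14 recombinant inbred lines
(190 plants). They parameterize the synthetic-data generator, seed worked
examples, and let the statistics layer be exercised against the printed
columns derived from them (replicate numbers, source-of-variation
percentages, heritability inputs).

Units: weights mg, lengths cm, diameters mm, angles degrees, branching
density per cm; CVs and percentages in percent.
"""

from __future__ import annotations

import pandas as pd

# Single-genotype (R-o-18) environmental screen: per trait the mean, CV (%),
# and REML SDs of the run, scanner-within-run, and residual effects.
RO18_SCREEN = pd.DataFrame(
    [
        # trait, mean, cv, sd_run, sd_scanner, sd_residual
        ("shoot_fresh_weight", 116.6, 23.1, 27.22, 18.36, 19.22),
        ("shoot_dry_weight", 9.1, 19.9, 0.68, 1.20, 1.32),
        ("root_fresh_weight", 35.4, 40.7, 4.17, 10.91, 9.31),
        ("root_dry_weight", 3.2, 33.5, 0.62, 0.79, 0.70),
        ("primary_root_length", 12.0, 31.4, 3.05, 1.83, 3.17),
        ("primary_root_diameter", 0.49, 9.7, 0.070, 0.000, 0.047),
        ("lateral_branching_density", 2.61, 36.8, 0.451, 0.613, 0.713),
        ("lateral_root_length", 2.90, 83.2, 1.96, 0.00, 2.33),
        ("lateral_root_diameter", 0.38, 7.6, 0.080, 0.010, 0.026),
        ("lateral_insertion_angle", 77.3, 5.8, 1.58, 1.45, 4.15),
        ("total_lateral_root_length", 101.3, 40.3, 29.7, 27.6, 29.9),
        ("total_root_length", 112.0, 37.1, 29.5, 28.4, 30.2),
    ],
    columns=["trait", "mean", "cv", "sd_run", "sd_scanner", "sd_residual"],
)

# Multi-genotype (BraIRRI) screen: REML SDs of genotype, genotype x run,
# genotype x scanner, genotype x run x scanner, and residual effects.
BRAIRRI_SCREEN = pd.DataFrame(
    [
        # trait, mean, sd_g, sd_gr, sd_gs, sd_grs, sd_residual
        ("shoot_fresh_weight", 53.4, 19.58, 9.17, 1.38, 0.00, 10.10),
        ("shoot_dry_weight", 3.1, 1.02, 0.66, 0.00, 0.00, 0.61),
        ("root_fresh_weight", 12.5, 2.94, 4.44, 0.00, 2.30, 3.32),
        ("root_dry_weight", 1.2, 0.32, 0.26, 0.00, 0.88, 0.56),
        ("primary_root_length", 16.4, 2.19, 1.18, 0.00, 1.24, 2.34),
        ("primary_root_diameter", 0.36, 0.019, 0.014, 0.007, 0.011, 0.019),
        ("lateral_branching_density", 2.82, 0.454, 0.322, 0.155, 0.000, 0.666),
        ("lateral_root_length", 1.28, 0.16, 0.44, 0.14, 0.16, 0.48),
        ("lateral_root_diameter", 0.27, 0.000, 0.040, 0.007, 0.022, 0.023),
        ("lateral_insertion_angle", 67.6, 3.12, 3.48, 1.62, 0.36, 4.18),
        ("total_lateral_root_length", 31.3, 8.09, 18.35, 1.99, 1.25, 9.15),
        ("total_root_length", 47.8, 9.73, 18.75, 1.23, 2.15, 9.45),
    ],
    columns=["trait", "mean", "sd_genotype", "sd_genotype_run", "sd_genotype_scanner",
             "sd_genotype_run_scanner", "sd_residual"],
)

# Logistic growth model for the BraIRRI screen: shared inflection (DAS) and
# scale (per day), genotype-specific asymptotes (cm).
LOGISTIC_TOTAL_ROOT = {
    "inflection_das": 10.4,
    "scale_per_day": 0.310,
    "asymptote_cm": {
        "IMB211": 37.3, "R500": 126.6, "IRRI_002": 64.2, "IRRI_016": 49.4,
        "IRRI_030": 47.8, "IRRI_070": 56.8, "IRRI_104": 55.9, "IRRI_124": 47.5,
        "IRRI_143": 61.1, "IRRI_198": 56.1, "IRRI_201": 53.5, "IRRI_205": 61.3,
        "IRRI_229": 67.6, "IRRI_248": 52.6, "IRRI_360": 71.5, "IRRI_380": 113.7,
    },
}

LOGISTIC_PRIMARY_ROOT = {
    "inflection_das": 8.82,
    "scale_per_day": 0.211,
    "asymptote_cm": {
        "IMB211": 17.4, "R500": 28.3, "IRRI_002": 22.3, "IRRI_016": 17.0,
        "IRRI_030": 22.9, "IRRI_070": 19.1, "IRRI_104": 17.1, "IRRI_124": 20.3,
        "IRRI_143": 25.4, "IRRI_198": 29.0, "IRRI_201": 26.5, "IRRI_205": 21.1,
        "IRRI_229": 22.5, "IRRI_248": 23.5, "IRRI_360": 19.1, "IRRI_380": 24.0,
    },
}

# Genotype-specific initial lateral elongation rates (cm per day at emergence
# day zero after transfer) from the quadratic rate model.
LATERAL_RATE_INTERCEPTS = {
    "IMB211": 0.255, "R500": 0.290, "IRRI_002": 0.255, "IRRI_016": 0.273,
    "IRRI_030": 0.307, "IRRI_070": 0.285, "IRRI_104": 0.326, "IRRI_124": 0.262,
    "IRRI_143": 0.216, "IRRI_198": 0.234, "IRRI_201": 0.263, "IRRI_205": 0.296,
    "IRRI_229": 0.295, "IRRI_248": 0.233, "IRRI_360": 0.281, "IRRI_380": 0.297,
}
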