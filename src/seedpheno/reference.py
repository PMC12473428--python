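"""Published ANOVA summaries from the motivating 43-clone conilon coffee trial.

The raw imaging data of that trial were not deposited; what is public is
the per-trait ANOVA summary (mean squares for blocks, genotypes and
residual, plus the residual coefficient of variation) from a randomized
complete block design with g = 43 genotypes and r = 4 replicates.
These summaries are sufficient inputs for every genetic-parameter
estimator in :mod:`seedpheno.anova`, so they double as worked examples:
feeding them through ``estimate_genetic_parameters`` reproduces the
trial's published heritabilities and variation indexes.

Values are keyed by trait id of :data:`seedpheno.traits.DEFAULT_SCHEMA`.
"""

from __future__ import annotations

REFERENCE_G = 43
REFERENCE_R = 4

# trait_id -> (ms_blocks, ms_genotypes, ms_residual, cv_pct)
REFERENCE_ANOVA = {
    # beans
    "b_area": (0.203, 0.334, 0.114, 8.048),
    "b_circularity": (0.0032, 0.0655, 0.0008, 1.25),
    "b_max_diameter": (0.0002, 0.0834, 0.00016, 1.612),
    "b_min_diameter": (0.00019, 0.0426, 0.00013, 1.994),
    "b_sphericity": (46.926, 126.24, 17.841, 20.644),
    "b_rectangularity": (0.00007, 0.0575, 0.00001, 0.5190),
    "b_irregularity": (0.00092, 0.0039, 0.00053, 30.043),
    "b_n_corners": (899.858, 14566.632, 439.630, 11.101),
    "b_perimeter": (0.088, 1.148, 0.041, 7.543),
    # cherries
    "c_area": (0.0203, 0.3348, 0.0114, 8.048),
    "c_circularity": (0.00242, 0.0810, 0.0016, 4.914),
    "c_max_diameter": (0.0024, 0.2619, 0.0040, 4.554),
    "c_min_diameter": (0.0040, 0.1624, 0.0034, 5.055),
    "c_sphericity": (391.160, 4691.685, 1357.386, 62.755),
    "c_rectangularity": (0.00016, 0.0558, 0.00029, 2.292),
    "c_irregularity": (0.0049, 0.0028, 0.0035, 28.710),
    "c_perimeter": (2.7311, 29.3073, 5.2493, 27.950),
}

# trait_id -> mean over the four published group means (trait units);
# used as plausible grand means when a mean is needed alongside the
# mean squares (e.g. to express CVg and CVe on their original scale).
REFERENCE_TRAIT_MEANS = {
    "b_area": 0.37975,
    "b_circularity": 0.74905,
    "b_max_diameter": 0.80395,
    "b_min_diameter": 0.587625,
    "b_sphericity": 22.65765,
    "b_rectangularity": 0.785825,
    "b_irregularity": 0.0898,
    "b_n_corners": 186.8061,
    "b_perimeter": 28.22925,
    "c_area": 13.3395,
    "c_circularity": 0.840625,
    "c_max_diameter": 14.245,
    "c_min_diameter": 11.73775,
    "c_sphericity": 51.59465,
    "c_rectangularity": 0.775025,
    "c_irregularity": 0.19115,
    "c_perimeter": 76.7515,
}
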