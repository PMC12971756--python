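"""Published model-comparison summaries for the Heliconia tortuosa study system.

The motivating field study of pollinator-mediated gene flow in
*Heliconia tortuosa* (Costa Rica) reports, for each response variable,
an AICc-ranked set of simple regressions on connectivity metrics: three
intra-patch metrics fitted to 30 sampling sites (13 for the
hummingbird-capture response), and the twelve-metric local landscape
factorial.  The printed AICc and Akaike-weight columns are reproduced
here as reference data: recomputing the weights from the AICc column
with :func:`pollenscape.models.akaike_weights` must agree with the
printed weights, which validates the multimodel-inference arithmetic
end to end.

AICc values are printed to 2 decimals and weights to 3; propagating the
input rounding bounds the achievable agreement at about one unit in the
weights' third decimal.
"""

from __future__ import annotations

import pandas as pd

# intra-patch model sets: (metric, slope, se, r2, aicc, delta_aicc, weight)
_INTRA = {
    "prop_high_mobility": [
        ("total_area", 0.617, 0.231, 0.392, 38.05, 2.17, 0.221),
        ("area_within_radius", 0.781, 0.242, 0.486, 35.88, 0.00, 0.654),
        ("distance_weighted", 0.698, 0.295, 0.340, 39.19, 3.31, 0.125),
    ],
    "h": [
        ("total_area", 0.470, 0.167, 0.221, 83.57, 0.00, 0.462),
        ("area_within_radius", 0.453, 0.168, 0.205, 84.15, 0.58, 0.345),
        ("distance_weighted", 0.417, 0.172, 0.174, 85.32, 1.75, 0.192),
    ],
    "tm_minus_ts": [
        ("total_area", -0.373, 0.175, 0.139, 86.56, 0.00, 0.466),
        ("area_within_radius", -0.346, 0.177, 0.120, 87.22, 0.66, 0.334),
        ("distance_weighted", -0.298, 0.180, 0.089, 88.25, 1.69, 0.200),
    ],
}

# local factorial: (habitat_def, weighting, gap_mode, slope, se, r2, aicc,
# delta_aicc, weight); row order narrow/broad x unweighted/kernel x
# unlimited/threshold/probabilistic
_LOCAL = {
    "prop_high_mobility": [
        ("narrow", "unweighted", "unlimited", 0.513, 0.192, 0.393, 38.03, 0.00, 0.187),
        ("narrow", "unweighted", "threshold", 0.496, 0.200, 0.359, 38.73, 0.71, 0.131),
        ("narrow", "unweighted", "probabilistic", 0.459, 0.187, 0.354, 38.84, 0.81, 0.125),
        ("narrow", "kernel", "unlimited", 0.431, 0.185, 0.330, 39.32, 1.29, 0.098),
        ("narrow", "kernel", "threshold", 0.451, 0.204, 0.309, 39.72, 1.69, 0.080),
        ("narrow", "kernel", "probabilistic", 0.441, 0.199, 0.308, 39.72, 1.69, 0.080),
        ("broad", "unweighted", "unlimited", 0.519, 0.274, 0.246, 40.86, 2.83, 0.045),
        ("broad", "unweighted", "threshold", 0.536, 0.270, 0.264, 40.54, 2.51, 0.053),
        ("broad", "unweighted", "probabilistic", 0.518, 0.242, 0.295, 39.98, 1.95, 0.070),
        ("broad", "kernel", "unlimited", 0.472, 0.249, 0.246, 40.85, 2.82, 0.046),
        ("broad", "kernel", "threshold", 0.440, 0.254, 0.214, 41.38, 3.36, 0.035),
        ("broad", "kernel", "probabilistic", 0.469, 0.241, 0.255, 40.68, 2.66, 0.049),
    ],
    "h": [
        ("narrow", "unweighted", "unlimited", 0.157, 0.157, 0.025, 90.29, 3.83, 0.037),
        ("narrow", "unweighted", "threshold", 0.051, 0.051, 0.003, 90.96, 4.50, 0.026),
        ("narrow", "unweighted", "probabilistic", 0.136, 0.136, 0.018, 90.48, 4.02, 0.034),
        ("narrow", "kernel", "unlimited", 0.100, 0.100, 0.010, 90.74, 4.28, 0.030),
        ("narrow", "kernel", "threshold", 0.044, 0.044, 0.002, 90.98, 4.52, 0.026),
        ("narrow", "kernel", "probabilistic", 0.090, 0.090, 0.008, 90.80, 4.34, 0.029),
        ("broad", "unweighted", "unlimited", 0.242, 0.183, 0.059, 89.23, 2.77, 0.063),
        ("broad", "unweighted", "threshold", 0.250, 0.183, 0.063, 89.10, 2.64, 0.067),
        ("broad", "unweighted", "probabilistic", 0.376, 0.175, 0.142, 86.46, 0.00, 0.251),
        ("broad", "kernel", "unlimited", 0.283, 0.181, 0.080, 88.53, 2.07, 0.089),
        ("broad", "kernel", "threshold", 0.320, 0.179, 0.102, 87.80, 1.34, 0.129),
        ("broad", "kernel", "probabilistic", 0.366, 0.176, 0.134, 86.73, 0.27, 0.220),
    ],
    "tm_minus_ts": [
        ("narrow", "unweighted", "unlimited", -0.224, 0.184, 0.050, 89.50, 3.48, 0.043),
        ("narrow", "unweighted", "threshold", -0.156, 0.187, 0.024, 90.30, 4.28, 0.029),
        ("narrow", "unweighted", "probabilistic", -0.157, 0.187, 0.025, 90.29, 4.27, 0.029),
        ("narrow", "kernel", "unlimited", -0.140, 0.187, 0.019, 90.45, 4.43, 0.027),
        ("narrow", "kernel", "threshold", -0.083, 0.188, 0.007, 90.83, 4.81, 0.022),
        ("narrow", "kernel", "probabilistic", -0.088, 0.188, 0.008, 90.81, 4.79, 0.022),
        ("broad", "unweighted", "unlimited", -0.288, 0.181, 0.083, 88.45, 2.43, 0.073),
        ("broad", "unweighted", "threshold", -0.291, 0.181, 0.085, 88.39, 2.37, 0.075),
        ("broad", "unweighted", "probabilistic", -0.393, 0.174, 0.154, 86.02, 0.00, 0.244),
        ("broad", "kernel", "unlimited", -0.319, 0.179, 0.102, 87.83, 1.81, 0.099),
        ("broad", "kernel", "threshold", -0.351, 0.177, 0.124, 87.09, 1.06, 0.144),
        ("broad", "kernel", "probabilistic", -0.375, 0.175, 0.141, 86.49, 0.46, 0.194),
    ],
}


def intra_patch_table(response: str) -> pd.DataFrame:
    """Published intra-patch model set for one response variable."""
    return pd.DataFrame(
        _INTRA[response],
        columns=["metric", "beta", "se", "r2", "aicc", "delta_aicc", "weight"],
    )


def local_table(response: str) -> pd.DataFrame:
    """Published 12-model local landscape set for one response variable."""
    return pd.DataFrame(
        _LOCAL[response],
        columns=[
            "habitat_def",
            "weighting",
            "gap_mode",
            "beta",
            "se",
            "r2",
            "aicc",
            "delta_aicc",
            "weight",
        ],
    )


def all_model_sets() -> dict[tuple[str, str], pd.DataFrame]:
    """All six published model sets keyed by (response, scale)."""
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for response in _INTRA:
        out[(response, "intra_patch")] = intra_patch_table(response)
        out[(response, "local")] = local_table(response)
    return out
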