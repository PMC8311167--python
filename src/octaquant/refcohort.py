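"""Reference cohort summary statistics for simulation and validation.

Published group summaries (mean, SD) of foveal microvascular descriptors
from a clinical OCT-A cohort of 49 Parkinson's disease patients (87 eyes)
and 40 controls (73 eyes), per plexus. They serve two purposes here:

* as generator parameters, so simulated cohorts carry group shifts of
  clinically observed magnitude;
* as inputs to effect-size arithmetic (Cohen's d recomputed from the
  printed means and SDs, and the area/length consistency of the mean
  vessel diameter).

``d`` is the published standardized mean difference for the same row.
"""

from __future__ import annotations

#: (metric, plexus) -> {"PD": (mean, sd), "control": (mean, sd), "d": published d}
FOVEAL_REFERENCE = {
    ("faz_area_mm2", "SVC"): {"PD": (0.669, 0.214), "control": (0.824, 0.292), "d": 0.61},
    ("faz_area_mm2", "DVC"): {"PD": (0.401, 0.181), "control": (0.544, 0.198), "d": 0.75},
    ("faz_circularity", "SVC"): {"PD": (0.187, 0.038), "control": (0.194, 0.029), "d": 0.21},
    ("faz_circularity", "DVC"): {"PD": (0.257, 0.045), "control": (0.271, 0.043), "d": 0.32},
    ("lacunarity", "SVC"): {"PD": (6.0, 0.4), "control": (5.7, 0.4), "d": 0.75},
    ("lacunarity", "DVC"): {"PD": (12.8, 0.7), "control": (9.8, 3.2), "d": 1.30},
    ("fractal_dimension", "SVC"): {"PD": (1.42, 0.05), "control": (1.37, 0.09), "d": 0.69},
    ("fractal_dimension", "DVC"): {"PD": (1.49, 0.04), "control": (1.47, 0.04), "d": 0.50},
    ("perfusion_density", "SVC"): {"PD": (0.14, 0.04), "control": (0.11, 0.05), "d": 0.66},
    ("perfusion_density", "DVC"): {"PD": (0.22, 0.04), "control": (0.20, 0.05), "d": 0.44},
    ("skeleton_density", "SVC"): {"PD": (6.0, 1.9), "control": (4.8, 2.2), "d": 0.58},
    ("skeleton_density", "DVC"): {"PD": (8.6, 1.9), "control": (7.6, 1.8), "d": 0.54},
    ("vessel_perimeter_index", "SVC"): {"PD": (17.1, 4.8), "control": (13.6, 5.6), "d": 0.67},
    ("vessel_perimeter_index", "DVC"): {"PD": (27.6, 5.2), "control": (23.6, 5.6), "d": 0.74},
    ("vessel_diameter_um", "SVC"): {"PD": (23.3, 1.6), "control": (23.7, 2.1), "d": 0.21},
    ("vessel_diameter_um", "DVC"): {"PD": (26.1, 2.1), "control": (25.8, 2.0), "d": 0.15},
}

#: PD subgroups with/without mild cognitive impairment (18 vs 31 subjects)
MCI_SUBGROUP_REFERENCE = {
    ("faz_area_mm2", "SVC"): {"PD-MCI": (0.73, 0.20), "PD-NC": (0.63, 0.21), "d": 0.49},
    ("faz_circularity", "SVC"): {"PD-MCI": (0.17, 0.02), "PD-NC": (0.20, 0.04), "d": 0.95},
}

#: demographic/covariate structure of the same cohort
COVARIATE_REFERENCE = {
    "PD": {
        "n": 49, "age": (64.6, 7.9), "female_p": 0.347, "hypertension_p": 0.245,
        "moca": (24.4, 4.1), "updrs_iii": (27.7, 7.7), "duration": (7.1, 4.1),
    },
    "control": {
        "n": 40, "age": (62.1, 8.0), "female_p": 0.675, "hypertension_p": 0.175,
        "moca": (25.7, 2.5), "updrs_iii": None, "duration": None,
    },
}
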