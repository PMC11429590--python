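"""Published reference values for the two rapeseed vitamin-C crosses.

A published six-generation joint segregation analysis of vitamin C
content (mg/100 g fresh weight) in rapeseed seedlings, covering two
biparental crosses (A and B), selected MX2-A-AD — two additive major
genes plus additive-dominance polygenes — as the best-fitting model.
The tables below carry its printed descriptive statistics, first-order
effect estimates and second-order variance components.  They serve two
purposes here: they parameterize the bundled simulation presets (the
raw phenotypes behind the analysis were never deposited), and their
internal arithmetic identities (CV = 100*SD/mean, the variance
additivity sigma2_p = sigma2_e + sigma2_mg + sigma2_pg, heritability
percentages, the polygene dominance degree [h]/[d]) are recomputed by
the test suite and the acceptance script.

Erratum: the cross-B BC1P2 phenotypic variance was printed as 281.71 in
the variance-component table, which contradicts both the additivity
identity (67.07 + 147.33 + 73.31 = 287.71) and the descriptive table's
variance for that generation (287.71).  ``sigma2_p`` below carries the
corrected value; the printed one is kept as ``sigma2_p_printed``.
"""

from __future__ import annotations

#: descriptive statistics per cross and generation
PUBLISHED_SUMMARY: dict[str, dict[str, dict[str, float]]] = {
    "A": {
        "P1":    {"n": 50,  "min": 125.02, "max": 160.02, "mean": 141.24, "sd": 8.27,  "variance": 68.37,  "cv_percent": 5.85},
        "P2":    {"n": 50,  "min": 62.76,  "max": 90.27,  "mean": 78.58,  "sd": 7.26,  "variance": 52.64,  "cv_percent": 9.23},
        "F1":    {"n": 46,  "min": 96.64,  "max": 135.68, "mean": 112.22, "sd": 10.22, "variance": 104.54, "cv_percent": 9.11},
        "F2":    {"n": 217, "min": 57.70,  "max": 163.86, "mean": 101.00, "sd": 20.27, "variance": 410.95, "cv_percent": 20.07},
        "BC1P1": {"n": 128, "min": 78.25,  "max": 181.67, "mean": 125.52, "sd": 23.17, "variance": 536.94, "cv_percent": 18.46},
        "BC1P2": {"n": 123, "min": 55.30,  "max": 118.36, "mean": 87.40,  "sd": 14.76, "variance": 217.78, "cv_percent": 16.89},
    },
    "B": {
        "P1":    {"n": 50,  "min": 122.79, "max": 154.89, "mean": 139.34, "sd": 9.15,  "variance": 83.73,  "cv_percent": 6.57},
        "P2":    {"n": 50,  "min": 62.75,  "max": 89.02,  "mean": 74.30,  "sd": 7.30,  "variance": 53.24,  "cv_percent": 9.82},
        "F1":    {"n": 48,  "min": 99.74,  "max": 129.13, "mean": 112.94, "sd": 8.26,  "variance": 68.20,  "cv_percent": 7.31},
        "F2":    {"n": 245, "min": 47.23,  "max": 174.65, "mean": 94.37,  "sd": 23.64, "variance": 558.84, "cv_percent": 25.05},
        "BC1P1": {"n": 119, "min": 85.32,  "max": 170.50, "mean": 122.81, "sd": 19.77, "variance": 390.70, "cv_percent": 16.09},
        "BC1P2": {"n": 111, "min": 54.54,  "max": 123.66, "mean": 87.81,  "sd": 16.96, "variance": 287.71, "cv_percent": 19.32},
    },
}

#: first-order effect estimates of the selected MX2-A-AD model
PUBLISHED_FIRST_ORDER: dict[str, dict[str, float]] = {
    "A": {"m": 107.11, "d_a": 22.43, "d_b": -6.34,
          "poly_d": 19.65, "poly_h": -0.52, "dominance_degree": -0.03},
    "B": {"m": 103.92, "d_a": 30.72, "d_b": -9.61,
          "poly_d": 15.95, "poly_h": 3.20, "dominance_degree": 0.20},
}

#: second-order variance components and heritability percentages
PUBLISHED_VARIANCE_COMPONENTS: dict[str, dict[str, dict[str, float]]] = {
    "A": {
        "BC1P1": {"sigma2_p": 536.94, "sigma2_e": 71.93, "sigma2_mg": 225.76,
                  "sigma2_pg": 239.25, "h2_mg": 42.05, "h2_pg": 44.56,
                  "h2_total": 86.60, "env_fraction": 13.40},
        "BC1P2": {"sigma2_p": 217.78, "sigma2_e": 71.93, "sigma2_mg": 119.60,
                  "sigma2_pg": 26.25, "h2_mg": 54.92, "h2_pg": 12.05,
                  "h2_total": 66.97, "env_fraction": 33.03},
        "F2":    {"sigma2_p": 410.95, "sigma2_e": 71.93, "sigma2_mg": 339.02,
                  "sigma2_pg": 0.00, "h2_mg": 82.50, "h2_pg": 0.00,
                  "h2_total": 82.50, "env_fraction": 17.50},
    },
    "B": {
        "BC1P1": {"sigma2_p": 390.70, "sigma2_e": 67.07, "sigma2_mg": 289.72,
                  "sigma2_pg": 33.91, "h2_mg": 74.15, "h2_pg": 8.68,
                  "h2_total": 82.83, "env_fraction": 17.17},
        "BC1P2": {"sigma2_p": 287.71, "sigma2_p_printed": 281.71,
                  "sigma2_e": 67.07, "sigma2_mg": 147.33,
                  "sigma2_pg": 73.31, "h2_mg": 51.21, "h2_pg": 25.48,
                  "h2_total": 76.69, "env_fraction": 23.31},
        "F2":    {"sigma2_p": 558.84, "sigma2_e": 67.07, "sigma2_mg": 491.77,
                  "sigma2_pg": 0.00, "h2_mg": 88.00, "h2_pg": 0.00,
                  "h2_total": 88.00, "env_fraction": 12.00},
    },
}
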