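"""Bundled reference results: per-fold image-quality metrics on a pelvic cohort.

Five-fold cross-validation results for uncorrected CBCT, a
cycle-consistency baseline, and the contrastive translation model,
evaluated against same-day quality-assurance fan-beam CT on an
institutional pelvic dataset (102 volume pairs from 79 patients). Used by
the documentation and the fold-aggregation tooling as worked-example
inputs; per-fold axial slice counts are included.
"""

FOLD_SLICE_COUNTS = (2184, 2217, 2218, 2080, 2080)

# metric -> method -> per-fold values (folds 1..5)
PELVIC_CV_RESULTS: dict[str, dict[str, tuple[float, ...]]] = {
    "mae_hu": {
        "cbct": (35.24, 18.13, 26.61, 16.42, 15.7),
        "cyclegan": (34.10, 147.59, 23.70, 15.43, 14.76),
        "cut": (32.80, 15.24, 24.00, 14.28, 11.30),
    },
    "ssim": {
        "cbct": (0.77, 0.73, 0.80, 0.91, 0.77),
        "cyclegan": (0.76, 0.00, 0.79, 0.91, 0.77),
        "cut": (0.75, 0.76, 0.79, 0.92, 0.77),
    },
    "rmse_hu": {
        "cbct": (91.87, 48.57, 96.50, 44.05, 44.00),
        "cyclegan": (98.37, 437.41, 104.21, 51.54, 55.30),
        "cut": (105.01, 58.84, 97.85, 60.31, 49.55),
    },
    "fid": {
        "cbct": (52.96, 51.67, 46.62, 51.11, 45.48),
        "cyclegan": (34.97, 241.2, 32.32, 37.34, 33.77),
        "cut": (55.26, 20.20, 24.67, 36.19, 21.33),
    },
}

# published mean (standard error) summaries for the table above, 2 d.p.
PELVIC_CV_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "mae_hu": {"cbct": (22.42, 3.75), "cyclegan": (47.12, 25.36), "cut": (19.52, 3.94)},
    "ssim": {"cbct": (0.80, 0.03), "cyclegan": (0.65, 0.16), "cut": (0.80, 0.03)},
    "rmse_hu": {"cbct": (65.00, 11.97), "cyclegan": (149.37, 72.81), "cut": (74.31, 11.28)},
    "fid": {"cbct": (49.57, 1.48), "cyclegan": (75.92, 41.33), "cut": (31.53, 6.57)},
}
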