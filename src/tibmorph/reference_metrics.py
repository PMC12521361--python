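"""Published benchmark metrics for the slice-classification task.

Reference per-group precision / recall / F1 values reported for a
cross-validated slice classifier of the four tibial compartments on real
micro-CT cohorts (parathyroid-hormone dose groups, sciatic-neurectomy /
mechanical-loading groups, aged mice, and an external risedronate
cohort).  They serve as worked-example inputs for the metric layer: the
F1 cells must reproduce as the harmonic mean of the printed precision and
recall, and the headline per-class means must reproduce from the
internal-cohort F1 cells.
"""

from __future__ import annotations

CLASS_KEYS = ("epiphyseal", "growth_plate", "primary", "secondary")

# (dataset, group) -> class -> (precision, recall, f1)
REFERENCE_CELLS = {
    ("dataset1", "PTH0"): {
        "epiphyseal": (0.941, 0.986, 0.963), "growth_plate": (0.974, 0.943, 0.958),
        "primary": (0.912, 0.917, 0.914), "secondary": (0.994, 0.995, 0.995)},
    ("dataset1", "PTH20"): {
        "epiphyseal": (0.939, 0.969, 0.954), "growth_plate": (0.957, 0.932, 0.944),
        "primary": (0.933, 0.938, 0.935), "secondary": (0.994, 0.994, 0.994)},
    ("dataset1", "PTH40"): {
        "epiphyseal": (0.935, 0.957, 0.946), "growth_plate": (0.937, 0.922, 0.930),
        "primary": (0.901, 0.926, 0.913), "secondary": (0.996, 0.990, 0.993)},
    ("dataset1", "PTH80"): {
        "epiphyseal": (0.954, 0.968, 0.960), "growth_plate": (0.963, 0.935, 0.949),
        "primary": (0.934, 0.946, 0.940), "secondary": (0.992, 0.996, 0.994)},
    ("dataset2", "SN-0N"): {
        "epiphyseal": (0.958, 0.976, 0.967), "growth_plate": (0.969, 0.939, 0.954),
        "primary": (0.893, 0.919, 0.906), "secondary": (0.993, 0.995, 0.994)},
    ("dataset2", "SN-6N"): {
        "epiphyseal": (0.941, 0.961, 0.951), "growth_plate": (0.946, 0.926, 0.936),
        "primary": (0.912, 0.933, 0.922), "secondary": (0.994, 0.992, 0.993)},
    ("dataset2", "SN-12N"): {
        "epiphyseal": (0.948, 0.975, 0.961), "growth_plate": (0.962, 0.933, 0.947),
        "primary": (0.885, 0.910, 0.897), "secondary": (0.994, 0.994, 0.994)},
    ("dataset3", "19m"): {
        "epiphyseal": (0.947, 0.975, 0.960), "growth_plate": (0.962, 0.939, 0.950),
        "primary": (0.888, 0.914, 0.901), "secondary": (0.995, 0.993, 0.994)},
    ("external", "Ris15"): {
        "epiphyseal": (0.978, 0.996, 0.987), "growth_plate": (0.975, 0.947, 0.961),
        "primary": (0.910, 0.910, 0.910), "secondary": (0.997, 0.998, 0.997)},
    ("external", "Ris15+ML"): {
        "epiphyseal": (0.982, 0.997, 0.989), "growth_plate": (0.994, 0.960, 0.977),
        "primary": (0.950, 0.921, 0.935), "secondary": (0.995, 0.999, 0.997)},
}

# headline per-class F1 means over the internal (cross-validation) cohorts
HEADLINE_MEAN_F1 = {
    "epiphyseal": 0.96, "growth_plate": 0.95,
    "primary": 0.92, "secondary": 0.99,
}

INTERNAL_DATASETS = ("dataset1", "dataset2", "dataset3")


def internal_f1_cells(class_key: str) -> list[float]:
    """Printed F1 cells of one class over the internal cohorts."""
    return [cells[class_key][2] for (ds, _), cells in REFERENCE_CELLS.items()
            if ds in INTERNAL_DATASETS]
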