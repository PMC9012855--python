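"""Published benchmark result tables, embedded verbatim.

The original study evaluated the ten variants on eight disease datasets
(D1–D8) and printed accuracy, precision and recall tables in percent at
two decimal places, plus a one-way ANOVA summary.  The values below are
those printed numbers, stored exactly as published — no re-derivation —
so that the summary statistics (row averages, win counts, RPI, ANOVA)
can be recomputed from them without access to the underlying datasets.

Known internal inconsistencies of the published tables are preserved,
not repaired: the recall table's GMD average prints 76.80 while the
accompanying text says 76.84, and the K-means accuracy cells average to
64.21 although the published average row prints 64.22.
"""

from __future__ import annotations

VARIANTS = (
    "classic",
    "adaptive",
    "locally_adaptive",
    "fuzzy",
    "kmeans",
    "weight_adjusted",
    "hassanat",
    "gmd",
    "mutual",
    "ensemble",
)

DATASETS = ("D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8")

# rows = datasets D1..D8, columns = VARIANTS order above; percent, 2 dp
ACCURACY = [
    [76.35, 73.64, 69.59, 73.65, 39.86, 73.65, 85.14, 69.59, 71.62, 77.03],
    [58.87, 63.83, 58.87, 63.83, 47.52, 63.83, 67.38, 62.41, 65.96, 68.79],
    [75.25, 75.00, 75.51, 74.24, 68.18, 74.24, 76.26, 74.24, 74.24, 79.29],
    [79.51, 78.69, 76.23, 81.97, 68.85, 81.97, 80.33, 77.05, 80.33, 81.15],
    [96.26, 96.26, 98.40, 95.72, 67.38, 95.72, 96.79, 98.40, 95.72, 93.05],
    [96.92, 97.44, 97.95, 97.44, 64.10, 97.44, 96.41, 97.44, 94.87, 92.31],
    [73.88, 73.60, 75.00, 73.60, 68.82, 73.60, 75.56, 74.44, 74.44, 76.69],
    [90.38, 92.10, 90.03, 91.07, 89.00, 91.07, 91.07, 91.41, 90.72, 90.38],
]

PRECISION = [
    [80.90, 77.42, 77.11, 76.84, 51.52, 76.84, 86.96, 77.11, 73.53, 78.57],
    [39.13, 46.51, 42.65, 46.15, 34.15, 46.15, 52.78, 46.27, 50.00, 54.00],
    [62.16, 60.32, 60.61, 61.17, 49.12, 61.17, 63.48, 58.91, 60.75, 74.71],
    [82.98, 81.25, 77.55, 85.42, 75.00, 85.42, 84.78, 78.00, 78.57, 85.11],
    [100.00, 100.00, 100.00, 100.00, 67.38, 100.00, 100.00, 100.00, 100.00, 100.00],
    [100.00, 99.18, 98.40, 100.00, 64.10, 100.00, 99.17, 98.39, 100.00, 100.00],
    [60.00, 58.49, 60.00, 59.78, 50.75, 59.78, 62.63, 58.97, 62.07, 71.64],
    [98.98, 98.06, 97.52, 98.99, 97.49, 98.99, 98.99, 97.12, 98.99, 98.98],
]

RECALL = [
    [80.00, 80.00, 71.11, 81.11, 18.89, 81.11, 88.89, 71.11, 83.33, 85.56],
    [37.50, 41.67, 60.42, 37.50, 58.33, 37.50, 39.58, 64.58, 25.00, 56.25],
    [55.20, 60.80, 64.00, 50.40, 22.40, 50.40, 58.40, 60.80, 52.00, 52.00],
    [69.64, 69.64, 67.86, 73.21, 48.21, 73.21, 69.64, 69.64, 78.57, 71.43],
    [94.44, 94.44, 97.62, 93.65, 100.00, 93.65, 95.24, 97.62, 93.65, 89.68],
    [95.20, 96.80, 98.40, 96.00, 100.00, 96.00, 95.20, 97.60, 92.00, 88.00],
    [50.89, 55.36, 61.61, 49.11, 30.36, 49.11, 55.36, 61.61, 48.21, 42.86],
    [88.24, 91.40, 89.14, 89.14, 87.78, 89.14, 89.14, 91.40, 88.69, 88.24],
]

# published one-way ANOVA rows (variants as groups, datasets as observations)
ANOVA_REFERENCE = {
    "accuracy": {
        "between_SS": 2200.496,
        "within_SS": 10735.168,
        "df_between": 9,
        "df_within": 70,
        "F": 1.594,
        "p": 0.134,
    },
    "precision": {
        "between_SS": 2468.842,
        "within_SS": 28675.727,
        "df_between": 9,
        "df_within": 70,
        "F": 0.670,
        "p": 0.733,
    },
    "recall": {
        "between_SS": 1915.288,
        "within_SS": 35172.935,
        "df_between": 9,
        "df_within": 70,
        "F": 0.424,
        "p": 0.918,
    },
}
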