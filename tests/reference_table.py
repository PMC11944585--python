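"""Published benchmark of per-species classification metrics.

A ten-species fungal colony-classification study reported these
cross-validated one-vs-rest metrics (rates as percentages, F1 and MCC
dimensionless, all printed to 2 decimal places).  The table serves as an
identity oracle: the printed F1 must follow from the printed PPV and
sensitivity, every row must be reproducible from some non-negative integer
(TP, FN, FP, TN) quadruple, and the bottom averages must equal the
unweighted column means.
"""

# species: (sensitivity, specificity, accuracy, ppv, npv, f1, mcc)
BENCHMARK_ROWS: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "Alternaria alternata": (80.00, 99.51, 99.04, 80.00, 99.51, 0.80, 0.80),
    "Aspergillus baeticus": (20.00, 96.52, 83.61, 53.85, 85.60, 0.29, 0.26),
    "Aspergillus caespitosus": (12.86, 95.94, 81.93, 39.13, 84.44, 0.19, 0.14),
    "Aspergillus flavus": (60.00, 99.75, 98.80, 85.71, 99.02, 0.71, 0.71),
    "Aspergillus nidulans": (100.00, 89.38, 89.64, 18.87, 100.00, 0.32, 0.41),
    "Aspergillus ochraceus": (12.94, 98.18, 80.72, 64.71, 81.41, 0.22, 0.23),
    "Aspergillus protuberus": (97.14, 75.36, 79.04, 44.44, 99.24, 0.61, 0.56),
    "Aspergillus sydowii": (80.00, 86.96, 85.78, 55.45, 95.54, 0.65, 0.58),
    "Fusarium sporotrichioides": (90.00, 99.01, 98.80, 69.23, 99.75, 0.78, 0.78),
    "Penicillium chrysogenum": (100.00, 99.51, 99.52, 83.33, 100.00, 0.91, 0.91),
}

# printed unweighted averages over the ten species rows
BENCHMARK_AVERAGES = (65.29, 94.01, 89.69, 59.47, 94.45, 0.55, 0.54)
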