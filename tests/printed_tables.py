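"""Published per-miRNA (log2FC, unadjusted p, label) triples used as
classification anchors: the intervention-group pre/post comparison and the
intervention-vs-control comparison from the source study's result tables.

Two intervention-group magnitudes (1057, 1334) are obvious typographical
artifacts (missing decimal separators) but still classify "down" under the
stated rule, so they remain usable anchors. Rows whose printed pair
contradicts the stated rule (|log2FC| > 0.6 and p < 0.05) are listed
separately and excluded from concordance checks.
"""

# intervention group, pre vs post (n = 6)
INTERVENTION_ROWS = [
    ("miR-1287-5p", -0.971, 0.006, "down"),
    ("miR-1307-5p", 1.100, 0.007, "up"),
    ("miR-6882-5p", -0.931, 0.011, "down"),
    ("miR-5695", -1.627, 0.014, "down"),
    ("miR-641", -0.704, 0.016, "down"),
    ("miR-134-5p", -1057.0, 0.016, "down"),
    ("miR-409-3p", -0.790, 0.018, "down"),
    ("miR-378c", -0.727, 0.021, "down"),
    ("miR-451a", 0.634, 0.026, "up"),
    ("miR-193b-5p", -2.142, 0.026, "down"),
    ("miR-31-5p", -0.852, 0.027, "down"),
    ("miR-4753-3p", -2.238, 0.035, "down"),
    ("miR-124-3p", -3.046, 0.036, "down"),
    ("miR-143-3p", -0.685, 0.041, "down"),
    ("miR-654-3p", -1334.0, 0.042, "down"),
]

# intervention vs control comparison (all 16 rows)
GROUP_COMPARISON_ROWS = [
    ("miR-1287-5p", -0.926, 0.016, "down"),
    ("miR-1307-5p", 1.115, 0.020, "up"),
    ("miR-6882-5p", -0.187, 0.630, "no"),
    ("miR-5695", -0.796, 0.281, "no"),
    ("miR-641", 0.103, 0.720, "no"),
    ("miR-134-5p", -1.354, 0.004, "down"),
    ("miR-409-3p", -0.579, 0.098, "no"),
    ("miR-335-5p", -0.085, 0.701, "no"),
    ("miR-378c", -0.162, 0.620, "no"),
    ("miR-451a", 0.773, 0.035, "up"),
    ("miR-193b-5p", -3.050, 0.002, "down"),
    ("miR-31-5p", -0.430, 0.329, "no"),
    ("miR-4753-3p", -0.320, 0.799, "no"),
    ("miR-124-3p", -3.357, 0.025, "down"),
    ("miR-143-3p", -0.521, 0.180, "no"),
    ("miR-654-3p", -1.461, 0.040, "down"),
]

# printed label contradicts the stated rule; excluded from concordance.
# (group, mirna, log2fc, p_unadj, printed_label, label_under_rule)
DISCREPANT_ROWS = [
    # intervention group: |log2FC| below the 0.6 cutoff yet labeled down
    ("intervention", "miR-335-5p", -0.599, 0.019, "down", "no"),
    # control group: rule says down, printed label is "no"
    ("control", "miR-6882-5p", -0.639, 0.039, "no", "down"),
    ("control", "miR-641", -0.728, 0.004, "no", "down"),
    ("control", "miR-4753-3p", -1.853, 0.038, "no", "down"),
]

# control-group rows consistent with the rule (all labeled "no")
CONTROL_ROWS = [
    ("miR-1287-5p", 0.066, 0.824, "no"),
    ("miR-1307-5p", 0.054, 0.896, "no"),
    ("miR-5695", -0.759, 0.118, "no"),
    ("miR-134-5p", 0.360, 0.262, "no"),
    ("miR-409-3p", -0.140, 0.623, "no"),
    ("miR-335-5p", -0.431, 0.050, "no"),
    ("miR-378c", -0.571, 0.036, "no"),
    ("miR-451a", -0.028, 0.905, "no"),
    ("miR-193b-5p", 0.970, 0.087, "no"),
    ("miR-31-5p", -0.340, 0.304, "no"),
    ("miR-124-3p", 0.347, 0.747, "no"),
    ("miR-143-3p", -0.131, 0.648, "no"),
    ("miR-654-3p", 0.216, 0.642, "no"),
]

CONCORDANCE_ROWS = INTERVENTION_ROWS + GROUP_COMPARISON_ROWS
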