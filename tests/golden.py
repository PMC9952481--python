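"""Frozen reference values for the bundled brain-tumour case study.

All values are transcribed from the case study's reference tables (4-decimal
display) or hand-computed from its stated formulas; tests compare against
them at the table tolerance of 5e-4 unless a value is exact.

Tuple order everywhere: p1..p4 = the Cartesian product of the sub-parameter
sets; alternative order: craniopharyngioma, brain-metastases,
medulloblastomas.
"""

# psi grades per decision maker and tuple (exact two- or three-decimal values)
PSI = {
    "Dm1": (0.15, 0.25, 0.35, 0.45),
    "Dm2": (0.51, 0.52, 0.53, 0.54),
    "Dm3": (0.54, 0.53, 0.52, 0.295),
}

# CFN components (w1, w2) of every opinion entry, per expert
CFN_TABLES = {
    "Dm1": [
        [(0.005, 0.135), (0.005, 0.155), (0.015, 0.175)],
        [(0.005, 0.235), (0.005, 0.255), (0.015, 0.275)],
        [(0.005, 0.335), (0.005, 0.355), (0.015, 0.375)],
        [(0.005, 0.435), (0.005, 0.455), (0.015, 0.475)],
    ],
    "Dm2": [
        [(0.05, 0.36), (0.05, 0.56), (0.15, 0.76)],
        [(0.05, 0.37), (0.05, 0.57), (0.15, 0.77)],
        [(0.05, 0.38), (0.05, 0.58), (0.15, 0.78)],
        [(0.05, 0.39), (0.05, 0.59), (0.15, 0.79)],
    ],
    "Dm3": [
        [(0.05, 0.39), (0.05, 0.59), (0.15, 0.79)],
        [(0.05, 0.38), (0.05, 0.58), (0.15, 0.78)],
        [(0.05, 0.37), (0.05, 0.57), (0.15, 0.77)],
        [(0.195, 0.375), (0.045, 0.155), (0.015, 0.425)],
    ],
}

# Weighted fuzzy matrices as displayed in the reference tables.  One cell of
# Dm2 — row p2, column a3, printed 0.3224 — omits the final halving of the
# fuzzy-value map; the formula-strict value is 0.1612 (see WEIGHTED_STRICT).
WEIGHTED_PRINTED = {
    "Dm1": [
        [0.0098, 0.0113, 0.0120],
        [0.0288, 0.0313, 0.0325],
        [0.0578, 0.0613, 0.0630],
        [0.0968, 0.1013, 0.1035],
    ],
    "Dm2": [
        [0.0791, 0.1301, 0.1556],
        [0.0832, 0.1352, 0.3224],
        [0.0875, 0.1405, 0.1670],
        [0.0918, 0.1458, 0.1728],
    ],
    "Dm3": [
        [0.0918, 0.1458, 0.1728],
        [0.0875, 0.1405, 0.1670],
        [0.0832, 0.1352, 0.1612],
        [0.0266, 0.0163, 0.0605],
    ],
}

ERRATUM_CELL = ("Dm2", 1, 2)  # expert, tuple index, alternative index
ERRATUM_PRINTED = 0.3224
ERRATUM_STRICT = 0.1612

# Core matrix as displayed (sums of the printed weighted matrices; inherits
# the 0.3224 slip in row p2, column a3)
CORE_PRINTED = [
    [0.1807, 0.2872, 0.3404],
    [0.1995, 0.3070, 0.5219],
    [0.2285, 0.3370, 0.3912],
    [0.2152, 0.2634, 0.3368],
]

CORE_ERRATUM_CELL = (1, 2)
CORE_ERRATUM_STRICT = 0.3607  # 0.0325 + 0.1612 + 0.1670

# Reference scores computed from the printed core matrix
SCORES_FROM_PRINTED_CORE = {
    "arithmetic": (0.2060, 0.2987, 0.3976),
    "geometric": (0.2052, 0.2974, 0.3911),
    "harmonic": (0.2044, 0.2962, 0.3854),
    "median": (0.2074, 0.2971, 0.3658),
}

TABLE_TOL = 5e-4  # printed tables round half-up at 4 decimals


# ---------------------------------------------------------------------------
# Golden union/intersection example: two structures over four alternatives
# and the four tuples of a (2, 2, 1) parameter space, with their published
# union (U3) and intersection (U4), transcribed entry for entry.
# Entry layout per tuple: [a1, a2, a3, a4], each CIFN as (at, bt, af, bf).

UI_SPACE = {
    "parameters": ("e1", "e2", "e3"),
    "sub_sets": (("e11", "e12"), ("e21", "e22"), ("e31",)),
}
UI_TUPLES = [
    ("e11", "e21", "e31"),
    ("e11", "e22", "e31"),
    ("e12", "e21", "e31"),
    ("e12", "e22", "e31"),
]
UI_ALTS = ("a1", "a2", "a3", "a4")

U1_PSI = (0.11, 0.31, 0.51, 0.61)
U1 = [
    [(0.21, 0.32, 0.31, 0.42), (0.41, 0.52, 0.51, 0.62), (0.61, 0.72, 0.31, 0.82), (0.81, 0.42, 0.11, 0.62)],
    [(0.71, 0.42, 0.11, 0.32), (0.61, 0.52, 0.21, 0.32), (0.51, 0.62, 0.21, 0.52), (0.41, 0.42, 0.31, 0.52)],
    [(0.81, 0.62, 0.11, 0.52), (0.71, 0.52, 0.21, 0.42), (0.61, 0.62, 0.11, 0.12), (0.51, 0.32, 0.31, 0.62)],
    [(0.51, 0.12, 0.11, 0.12), (0.41, 0.22, 0.31, 0.22), (0.31, 0.12, 0.11, 0.52), (0.21, 0.62, 0.41, 0.62)],
]

U2_PSI = (0.12, 0.32, 0.52, 0.62)
U2 = [
    [(0.22, 0.31, 0.32, 0.41), (0.42, 0.51, 0.52, 0.61), (0.62, 0.71, 0.32, 0.81), (0.82, 0.41, 0.12, 0.61)],
    [(0.72, 0.41, 0.12, 0.31), (0.62, 0.51, 0.22, 0.31), (0.52, 0.61, 0.22, 0.51), (0.42, 0.41, 0.32, 0.51)],
    [(0.82, 0.61, 0.12, 0.51), (0.72, 0.51, 0.22, 0.41), (0.62, 0.61, 0.12, 0.11), (0.52, 0.31, 0.32, 0.61)],
    [(0.52, 0.11, 0.12, 0.11), (0.42, 0.21, 0.32, 0.21), (0.32, 0.11, 0.12, 0.51), (0.22, 0.61, 0.42, 0.61)],
]

UNION_PSI = (0.12, 0.32, 0.52, 0.62)
UNION = [
    [(0.22, 0.32, 0.31, 0.42), (0.42, 0.52, 0.51, 0.62), (0.62, 0.72, 0.31, 0.82), (0.82, 0.42, 0.11, 0.62)],
    [(0.72, 0.42, 0.11, 0.32), (0.62, 0.52, 0.21, 0.32), (0.52, 0.62, 0.21, 0.52), (0.42, 0.42, 0.31, 0.52)],
    [(0.82, 0.62, 0.11, 0.52), (0.72, 0.52, 0.21, 0.42), (0.62, 0.62, 0.11, 0.12), (0.52, 0.32, 0.31, 0.62)],
    [(0.52, 0.12, 0.11, 0.12), (0.42, 0.22, 0.31, 0.22), (0.32, 0.12, 0.11, 0.52), (0.22, 0.62, 0.41, 0.62)],
]

INTERSECTION_PSI = (0.11, 0.31, 0.51, 0.61)
INTERSECTION = [
    [(0.21, 0.31, 0.32, 0.41), (0.41, 0.51, 0.52, 0.61), (0.61, 0.71, 0.32, 0.81), (0.81, 0.41, 0.12, 0.61)],
    [(0.71, 0.41, 0.12, 0.31), (0.61, 0.51, 0.22, 0.31), (0.51, 0.61, 0.22, 0.51), (0.41, 0.41, 0.32, 0.51)],
    [(0.81, 0.61, 0.12, 0.51), (0.71, 0.51, 0.22, 0.41), (0.61, 0.61, 0.12, 0.11), (0.51, 0.31, 0.32, 0.61)],
    [(0.51, 0.11, 0.12, 0.11), (0.41, 0.21, 0.32, 0.21), (0.31, 0.11, 0.12, 0.51), (0.21, 0.61, 0.42, 0.61)],
]
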