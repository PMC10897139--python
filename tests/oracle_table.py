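"""Independent hand re-encoding of the normalization band table.

Deliberately written in a different style from the implementation (literal
per-parameter chains over (threshold, score) rows, evaluated cell by cell)
so it can serve as an oracle for exhaustive grid scans.
"""

# nine "smaller is better" rows: value < t gives the score, except the last
# entry which is value <= t; anything larger scores 0.
STRICT_UPPER = {
    "conductivity": [(750, 100), (1000, 90), (1250, 80), (1500, 70), (2000, 60),
                     (2500, 50), (3000, 40), (5000, 30), (8000, 20)],
    "turbidity": [(5, 100), (10, 90), (15, 80), (20, 70), (25, 60),
                  (30, 50), (40, 40), (60, 30), (80, 20)],
    "nitrite": [(0.005, 100), (0.01, 90), (0.03, 80), (0.05, 70), (0.10, 60),
                (0.15, 50), (0.20, 40), (0.25, 30), (0.50, 20)],
    "nitrate": [(0.5, 100), (2.0, 90), (4.0, 80), (6.0, 70), (8.0, 60),
                (10.0, 50), (15.0, 40), (20.0, 30), (50.0, 20)],
    "ammonium": [(0.01, 100), (0.05, 90), (0.10, 80), (0.20, 70), (0.30, 60),
                 (0.40, 50), (0.50, 40), (0.75, 30), (1.00, 20)],
    "hardness": [(25, 100), (100, 90), (200, 80), (300, 70), (400, 60),
                 (500, 50), (600, 40), (800, 30), (1000, 20)],
    "chloride": [(25, 100), (50, 90), (100, 80), (150, 70), (200, 60),
                 (300, 50), (500, 40), (700, 30), (1000, 20)],
    "sulfate": [(25, 100), (50, 90), (75, 80), (100, 70), (150, 60),
                (250, 50), (400, 40), (600, 30), (1000, 20)],
    "total_coliforms": [(50, 100), (500, 90), (1000, 80), (2000, 70), (3000, 60),
                        (4000, 50), (5000, 40), (7000, 30), (10000, 20)],
}
INCLUSIVE_TEN = {
    "conductivity": 12000, "turbidity": 100, "nitrite": 1.00, "nitrate": 100.0,
    "ammonium": 1.25, "hardness": 1500, "chloride": 1500, "sulfate": 1500,
    "total_coliforms": 14000,
}

# dissolved oxygen ("larger is better"): (threshold, inclusive?, score)
DO_CHAIN = [(7.5, True, 100), (7.0, False, 90), (6.5, False, 80), (6.0, False, 70),
            (5.0, False, 60), (4.0, False, 50), (3.5, False, 40), (3.0, False, 30),
            (2.0, False, 20), (1.0, True, 10)]

# closed intervals, first match from the best score down
TEMP_CHAIN = [((16, 21), 100), ((15, 22), 90), ((14, 24), 80), ((12, 26), 70),
              ((10, 28), 60), ((5, 30), 50), ((0, 32), 40), ((-2, 36), 30),
              ((-4, 40), 20), ((-6, 45), 10)]
PH_CHAIN = [((7, 8), 100), ((7, 8.5), 90), ((7, 9), 80), ((6.5, 7), 70),
            ((6, 9.5), 60), ((5, 10), 50), ((4, 11), 40), ((3, 12), 30),
            ((2, 13), 20), ((1, 14), 10)]

# value domains for scanning/sampling, wide enough to hit every band
DOMAINS = {
    "conductivity": (0.0, 20000.0),
    "dissolved_oxygen": (0.0, 15.0),
    "turbidity": (0.0, 150.0),
    "nitrite": (0.0, 2.0),
    "nitrate": (0.0, 150.0),
    "ammonium": (0.0, 2.0),
    "hardness": (0.0, 2500.0),
    "chloride": (0.0, 2500.0),
    "sulfate": (0.0, 2500.0),
    "total_coliforms": (0.0, 20000.0),
    "temperature": (-10.0, 50.0),
    "ph": (0.0, 14.0),
}

WEIGHTS = {"conductivity": 2, "dissolved_oxygen": 4, "turbidity": 2, "nitrite": 2,
           "nitrate": 2, "ammonium": 3, "hardness": 1, "chloride": 1, "sulfate": 2,
           "total_coliforms": 3, "temperature": 1, "ph": 1}


def oracle_ci(param: str, value: float) -> int:
    """Score one value by reading the table cell by cell."""
    if param in STRICT_UPPER:
        for threshold, score in STRICT_UPPER[param]:
            if value < threshold:
                return score
        if value <= INCLUSIVE_TEN[param]:
            return 10
        return 0
    if param == "dissolved_oxygen":
        for threshold, inclusive, score in DO_CHAIN:
            if (value >= threshold) if inclusive else (value > threshold):
                return score
        return 0
    chain = TEMP_CHAIN if param == "temperature" else PH_CHAIN
    for (lo, hi), score in chain:
        if lo <= value <= hi:
            return score
    return 0


def oracle_wqi(values: dict) -> float:
    """Brute-force weighted mean over the 12 parameters."""
    num = sum(oracle_ci(p, v) * WEIGHTS[p] for p, v in values.items())
    den = sum(WEIGHTS[p] for p in values)
    return num / den
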