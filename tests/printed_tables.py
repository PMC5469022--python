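"""Published reference values frozen for cross-checking.

These are the printed per-gene cis-element counts (columns: ABRE, LTR,
TC-rich, TCA, HSE, TGACG, MBS), the printed dS/dN columns of the ten
duplicate pairs, and a few printed coordinate/translation rows of the
cotton SnRK2 family characterization this pipeline re-implements.
"""

CIS_ELEMENT_ORDER = ["ABRE", "LTR", "TC-rich", "TCA", "HSE", "TGACG", "MBS"]

# gene -> (a, b, c, d, e, f, g) counts
CIS_TABLE = {
    "GhSnRK2.1": (1, 0, 0, 1, 3, 1, 0),
    "GhSnRK2.2": (1, 1, 1, 1, 0, 0, 0),
    "GhSnRK2.3": (1, 1, 1, 1, 7, 0, 2),
    "GhSnRK2.4": (1, 1, 3, 2, 2, 2, 1),
    "GhSnRK2.5": (1, 0, 0, 1, 1, 0, 0),
    "GhSnRK2.6": (2, 0, 1, 1, 3, 0, 2),
    "GhSnRK2.7": (0, 0, 1, 4, 3, 1, 2),
    "GhSnRK2.8": (1, 0, 2, 2, 2, 4, 1),
    "GhSnRK2.9": (1, 0, 1, 0, 2, 2, 0),
    "GhSnRK2.10": (1, 0, 1, 2, 0, 0, 1),
    "GhSnRK2.11": (1, 0, 0, 0, 2, 2, 0),
    "GhSnRK2.12": (2, 1, 2, 2, 0, 2, 1),
    "GhSnRK2.13": (1, 0, 0, 2, 8, 0, 0),
    "GhSnRK2.14": (1, 1, 3, 2, 0, 0, 3),
    "GhSnRK2.15": (1, 0, 1, 1, 1, 4, 1),
    "GhSnRK2.16": (1, 0, 1, 0, 2, 2, 1),
    "GhSnRK2.17": (2, 0, 1, 1, 2, 2, 1),
    "GhSnRK2.18": (1, 0, 3, 2, 1, 2, 2),
    "GhSnRK2.19": (0, 1, 0, 0, 1, 0, 3),
    "GhSnRK2.20": (1, 0, 0, 1, 0, 0, 1),
}

# pair -> (identity %, dS, dN, printed dN/dS)
DNDS_TABLE = {
    "GhSnRK2.1/2.11": (97.78, 0.0812, 0.0101, 0.1247),
    "GhSnRK2.2/2.12": (93.18, 0.0570, 0.0261, 0.4582),
    "GhSnRK2.3/2.13": (99.72, 0.0234, 0.0012, 0.0522),
    "GhSnRK2.4/2.14": (98.53, 0.0374, 0.0066, 0.1765),
    "GhSnRK2.5/2.15": (99.44, 0.0240, 0.0012, 0.0521),
    "GhSnRK2.6/2.17": (97.36, 0.0434, 0.0113, 0.2613),
    "GhSnRK2.7/2.19": (99.72, 0.0258, 0.0013, 0.0492),
    "GhSnRK2.8/2.18": (98.83, 0.0216, 0.0052, 0.2386),
    "GhSnRK2.9/2.16": (98.89, 0.0074, 0.0050, 0.6781),
    "GhSnRK2.10/2.20": (99.17, 0.0235, 0.0037, 0.1577),
}

# (CDS length incl. stop, residue count) pairs from the printed table
TRANSLATION_PAIRS = [(1083, 360), (999, 332), (1092, 363)]

# (gene, chromosome, start, end, printed gene length)
COORDINATE_ROWS = [
    ("GhSnRK2.1", "A01", 447830, 450835, 3005),
    ("GhSnRK2.2", "A02", 16299920, 16301838, 1918),
    ("GhSnRK2.9", "scaffold2734_A11", 24966, 27913, 2947),
]
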