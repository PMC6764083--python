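"""Published reference values shipped as machine-readable fixtures.

These are the targets of the regression harness in :mod:`frec.evaluate`:
the verb-region log10 FRC column for the English paradigm, the full 9x6
encoding-cost grid, the Italian per-region prediction grids for both the
top-down and the memory-load model, the published mean reading times,
and the ordinal prediction tables juxtaposing the competing accounts.
The ordinal rows for the similarity, intervention and activation-decay
accounts are data for report juxtaposition only; those accounts are not
executable models here.
"""

from __future__ import annotations

ENGLISH_LABELS = (
    "D1-D2", "D1-N2", "D1-P2",
    "N1-D2", "N1-N2", "N1-P2",
    "P1-D2", "P1-N2", "P1-P2",
)

ITALIAN_LABELS = ("Art1-Art2", "Art1-Pro2", "Pro1-Art2", "Pro1-Pro2")

#: published mean reading times (ms) and standard errors at the verb
ENGLISH_READING_TIMES = {
    "D1-D2": (365, 19),
    "D1-N2": (319, 12),
    "D1-P2": (306, 14),
    "N1-D2": (348, 18),
    "N1-N2": (347, 21),
    "N1-P2": (291, 14),
    "P1-D2": (348, 18),
    "P1-N2": (311, 15),
    "P1-P2": (291, 13),
}

#: exact verb-region FRC values for the English conditions
ENGLISH_FRC = {
    "D1-D2": 27,
    "D1-N2": 12,
    "D1-P2": 6,
    "N1-D2": 18,
    "N1-N2": 18,
    "N1-P2": 4,
    "P1-D2": 18,
    "P1-N2": 8,
    "P1-P2": 4,
}

#: published log10(FRC) column (2 decimals)
ENGLISH_LOG_FRC = {
    "D1-D2": 1.43,
    "D1-N2": 1.08,
    "D1-P2": 0.78,
    "N1-D2": 1.26,
    "N1-N2": 1.26,
    "N1-P2": 0.60,
    "P1-D2": 1.26,
    "P1-N2": 0.90,
    "P1-P2": 0.60,
}

#: published per-region encoding-cost grid for the English paradigm
#: (regions BE, DP1, C, DP2, VERB, SPILL)
ENGLISH_FEC_GRID = {
    "D1-D2": (1, 2, 1, 3, 2, 3),
    "D1-N2": (1, 2, 1, 1, 2, 3),
    "D1-P2": (1, 2, 1, 0, 2, 3),
    "N1-D2": (1, 1, 1, 2, 2, 3),
    "N1-N2": (1, 1, 1, 2, 2, 3),
    "N1-P2": (1, 1, 1, 0, 2, 3),
    "P1-D2": (1, 0, 1, 2, 2, 3),
    "P1-N2": (1, 0, 1, 1, 2, 3),
    "P1-P2": (1, 0, 1, 0, 2, 3),
}

#: exact verb-region FRC values for the Italian conditions (hypothesis H2)
ITALIAN_FRC = {
    "Art1-Art2": 27,
    "Art1-Pro2": 24,
    "Pro1-Art2": 27,
    "Pro1-Pro2": 48,
}

#: published Italian on-line top-down predictions (DP1, DP2, verb, PP)
ITALIAN_TOPDOWN_GRID = {
    "Art1-Art2": {"DP1": 2, "DP2": 3, "VERB": 3.43, "SPILL": 5},
    "Art1-Pro2": {"DP1": 2, "DP2": 4, "VERB": 3.38, "SPILL": 5},
    "Pro1-Art2": {"DP1": 3, "DP2": 3, "VERB": 3.43, "SPILL": 5},
    "Pro1-Pro2": {"DP1": 3, "DP2": 5, "VERB": 3.68, "SPILL": 5},
}

#: published Italian on-line memory-load predictions under A3
ITALIAN_MEMLOAD_GRID = {
    "Art1-Art2": {"DP1": 2, "DP2": 2, "VERB": 4, "SPILL": 4},
    "Art1-Pro2": {"DP1": 2, "DP2": 3, "VERB": 5, "SPILL": 4},
    "Pro1-Art2": {"DP1": 3, "DP2": 2, "VERB": 4, "SPILL": 4},
    "Pro1-Pro2": {"DP1": 3, "DP2": 3, "VERB": 5, "SPILL": 4},
}

#: ordinal predictions of the competing accounts on the English paradigm
ENGLISH_ORDINAL_PREDICTIONS = {
    "memory_load": {
        "D1-D2": "Hard", "D1-N2": "Medium", "D1-P2": "Easy",
        "N1-D2": "Hard", "N1-N2": "Medium", "N1-P2": "Easy",
        "P1-D2": "Hard", "P1-N2": "Medium", "P1-P2": "Easy",
    },
    "similarity": {
        "D1-D2": "Hard", "D1-N2": "Medium", "D1-P2": "Easy",
        "N1-D2": "Medium", "N1-N2": "Hard", "N1-P2": "Easy",
        "P1-D2": "Easy", "P1-N2": "Easy", "P1-P2": "Medium",
    },
    "intervention": {
        "D1-D2": "Hard", "D1-N2": "?", "D1-P2": "Easy",
        "N1-D2": "?", "N1-N2": "Hard", "N1-P2": "Easy",
        "P1-D2": "Easy", "P1-N2": "Easy", "P1-P2": "Easy",
    },
    "act_r": {
        "D1-D2": "Hard", "D1-N2": "Hard", "D1-P2": "Medium",
        "N1-D2": "Hard", "N1-N2": "Hard", "N1-P2": "Medium",
        "P1-D2": "Medium", "P1-N2": "Medium", "P1-P2": "Easy",
    },
    "top_down": {
        "D1-D2": "Hardest", "D1-N2": "Medium", "D1-P2": "Medium-Easy",
        "N1-D2": "Hard", "N1-N2": "Hard", "N1-P2": "Easy",
        "P1-D2": "Hard", "P1-N2": "Medium", "P1-P2": "Easy",
    },
}

#: ordinal (off-line) predictions of the competing accounts on the Italian paradigm
ITALIAN_ORDINAL_PREDICTIONS = {
    "similarity": {
        "Art1-Art2": "Hard", "Pro1-Pro2": "Hard",
        "Art1-Pro2": "Medium", "Pro1-Art2": "Medium",
    },
    "intervention": {
        "Art1-Art2": "Hard", "Pro1-Pro2": "Hard",
        "Art1-Pro2": "Medium", "Pro1-Art2": "Medium",
    },
    "top_down_H1": {
        "Art1-Art2": "Hard", "Pro1-Pro2": "Hard",
        "Art1-Pro2": "Medium", "Pro1-Art2": "Medium",
    },
    "top_down_H2": {
        "Art1-Art2": "Hard", "Pro1-Pro2": "Hardest",
        "Art1-Pro2": "Medium", "Pro1-Art2": "Hard",
    },
    "memory_load_A1": {
        "Art1-Art2": "Hard", "Pro1-Pro2": "Hard",
        "Art1-Pro2": "Hard", "Pro1-Art2": "Hard",
    },
    "memory_load_A2": {
        "Art1-Art2": "Harder", "Pro1-Pro2": "Hard",
        "Art1-Pro2": "Hard", "Pro1-Art2": "Harder",
    },
    "memory_load_A3": {
        "Art1-Art2": "Hard", "Pro1-Pro2": "Harder",
        "Art1-Pro2": "Harder", "Pro1-Art2": "Hard",
    },
    "act_r": {
        "Art1-Art2": "Hard", "Pro1-Pro2": "Hard",
        "Art1-Pro2": "Hard", "Pro1-Art2": "Hard",
    },
}

#: ordinal difficulty scale, hardest first
ORDINAL_SCALE = ("Hardest", "Harder", "Hard", "Medium", "Medium-Easy", "Easy")
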