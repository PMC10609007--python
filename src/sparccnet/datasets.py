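"""Small built-in datasets used as worked examples.

``diet_study_zvalues`` is the betweenness z-value table of nine genus-level
taxa across the five diet-group gut networks of a mouse NAFLD feeding study
(ND normal diet, WD Western diet, PC/PG/CG anthocyanin-metabolite
supplements).  It is the canonical worked example for the keystone filter:
taxa with z > 2 within a group's network are that group's keystones.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["diet_study_zvalues", "DIET_GROUPS"]

DIET_GROUPS = ("ND", "WD", "PC", "PG", "CG")

_ROWS = [
    ("f_[Paraprevotellaceae]; g_[Prevotella]", 1.69, 3.45, -0.55, 0.07, 0.13),
    ("f_S24-7; g_", 0.78, -0.07, 2.24, 0.14, 1.65),
    ("f_Staphylococcaceae; g_Staphylococcus", -0.78, -0.32, 0.12, 2.03, -0.35),
    ("f_Dehalobacteriaceae; g_Dehalobacterium", 3.84, -0.65, -1.47, -0.41, -0.22),
    ("f_Lachnospiraceae;_", 0.24, 0.69, 3.05, 0.43, 1.12),
    ("f_Lachnospiraceae; g_[Ruminococcus]", 0.41, -0.46, 1.22, 0.14, 2.97),
    ("f_Alcaligenaceae; g_Sutterella", -0.75, -0.62, -0.89, -0.08, 2.70),
    ("f_Desulfovibrionaceae;g_", 2.51, -0.26, 0.82, 4.40, 0.48),
    ("f_Enterobacteriaceae; g_Escherichia", 2.38, 0.23, 0.37, -0.41, 0.09),
]


def diet_study_zvalues() -> pd.DataFrame:
    """Betweenness z-values (taxa × diet groups) of the worked example.

    Returns a DataFrame indexed by taxonomy string with one column per group.
    """
    return pd.DataFrame(
        [r[1:] for r in _ROWS],
        index=pd.Index([r[0] for r in _ROWS], name="taxonomy"),
        columns=list(DIET_GROUPS),
    )
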