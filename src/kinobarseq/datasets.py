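"""Published summary tables from the yeast human-kinome toxicity screen.

These small tables are the screen's reported end points and serve as
reference inputs: the 28 human kinases that are strongly toxic when
overexpressed in yeast, the per-kinase counts of suppressor interactions
and of suppressors with a human ortholog, and the spot-assay retest
fractions used to gauge agreement with the pooled Bar-seq calls.
"""

from __future__ import annotations

import pandas as pd

#: Human kinase genes strongly toxic when overexpressed in yeast.
TOXIC_KINASES: tuple[str, ...] = (
    "ABL1", "ACVR1", "AGK", "ASCIZ", "AURKB", "BRD4", "BRSK2",
    "CKMT1A", "COL4A3BP", "DYRK3", "EPHA4", "FASTKD5", "FGR",
    "IKBKE", "MAP4K3", "MAPK9", "MARK2", "MGC42105", "PAK1",
    "PAK2", "PIK3CB", "PRKCE", "PRKCQ", "SH3BP5L", "SRC",
    "TGFBR3", "TSSK2", "ZAK",
)

# per kinase: suppressor calls (Z > 1.96) and suppressor-derived
# interactions with a human ortholog
_PARTNER_COUNTS: dict[str, tuple[int, int]] = {
    "ABL1": (124, 41), "ACVR1": (23, 6), "AGK": (138, 49),
    "ASCIZ": (60, 18), "AURKB": (203, 75), "BRD4": (40, 14),
    "BRSK2": (27, 9), "CKMT1A": (164, 56), "COL4A3BP": (54, 24),
    "DYRK3": (120, 33), "EPHA4": (35, 11), "FASTKD5": (138, 45),
    "FGR": (134, 46), "IKBKE": (189, 66), "MAP4K3": (22, 5),
    "MAPK9": (45, 17), "MARK2": (103, 32), "MGC42105": (10, 5),
    "PAK1": (402, 131), "PAK2": (135, 45), "PIK3CB": (14, 1),
    "PRKCE": (31, 9), "PRKCQ": (322, 126), "SH3BP5L": (25, 12),
    "SRC": (211, 63), "TGFBR3": (33, 11), "TSSK2": (23, 6),
    "ZAK": (53, 13),
}

# spot-assay retests for five kinases: (kinase, group) -> (confirmed, tested);
# kinases not retested in a group (or with no enhancer called) have no entry
_SPOT_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("IKBKE", "suppressor"): (10, 10),
    ("MAPK9", "suppressor"): (6, 10),
    ("PAK1", "suppressor"): (32, 41),
    ("PAK2", "suppressor"): (13, 17),
    ("PRKCQ", "suppressor"): (10, 10),
    ("IKBKE", "non_modifier"): (0, 5),
    ("MAPK9", "non_modifier"): (2, 5),
    ("PRKCQ", "non_modifier"): (3, 5),
    ("IKBKE", "enhancer"): (0, 3),
    ("PAK2", "enhancer"): (1, 1),
    ("PRKCQ", "enhancer"): (3, 10),
}


def interaction_partner_counts() -> pd.DataFrame:
    """Per-kinase interaction tallies from the screen.

    Columns: kinase, n_suppressors (calls with Z > 1.96) and
    n_with_ortholog (suppressor-level interactions with a human ortholog);
    the latter column sums to the screen's total interaction count.
    """
    return pd.DataFrame(
        {
            "kinase": list(_PARTNER_COUNTS),
            "n_suppressors": [v[0] for v in _PARTNER_COUNTS.values()],
            "n_with_ortholog": [v[1] for v in _PARTNER_COUNTS.values()],
        }
    )


def spot_assay_counts() -> dict[tuple[str, str], tuple[int, int]]:
    """Spot-assay confirmation fractions, (kinase, group) → (confirmed, tested)."""
    return dict(_SPOT_COUNTS)
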