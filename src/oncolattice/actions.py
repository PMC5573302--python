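"""Shared phenotype (action) vocabulary for all agent types.

Quiescence is the default phenotype label; it becomes absorbing once a cell
*selects* it (or is forced into it by a blocked proliferation).
"""

from __future__ import annotations

__all__ = [
    "QUIESCENCE", "PROLIFERATION", "MIGRATION", "HYPOXIA", "NECROSIS",
    "APOPTOSIS", "BRANCH", "EXPANSION", "SPROUT",
    "ACTION_NAMES", "ACTION_CODES", "ALLOWED_ACTIONS", "allowed_actions",
]

(QUIESCENCE, PROLIFERATION, MIGRATION, HYPOXIA, NECROSIS, APOPTOSIS,
 BRANCH, EXPANSION, SPROUT) = range(9)

ACTION_NAMES = {
    QUIESCENCE: "quiescence", PROLIFERATION: "proliferation",
    MIGRATION: "migration", HYPOXIA: "hypoxia", NECROSIS: "necrosis",
    APOPTOSIS: "apoptosis", BRANCH: "branch", EXPANSION: "expansion",
    SPROUT: "sprout",
}
ACTION_CODES = {name: code for code, name in ACTION_NAMES.items()}

#: Per-type action sets: cancerous cells can starve (hypoxia/necrosis) but
#: not apoptose; healthy cells the reverse; tip cells lead sprouts (branch,
#: expansion); stalk cells follow and can start new sprouts.
ALLOWED_ACTIONS: dict[str, frozenset[str]] = {
    "cancerous": frozenset({"hypoxia", "necrosis", "migration",
                            "proliferation", "quiescence"}),
    "healthy": frozenset({"apoptosis", "migration", "proliferation",
                          "quiescence"}),
    "stalk": frozenset({"quiescence", "branch", "sprout"}),
    "tip": frozenset({"quiescence", "branch", "expansion"}),
}


def allowed_actions(celltype: str) -> frozenset[str]:
    """Action set of a cell type; raises on unknown types."""
    try:
        return ALLOWED_ACTIONS[celltype]
    except KeyError:
        raise ValueError(f"unknown cell type {celltype!r}") from None
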