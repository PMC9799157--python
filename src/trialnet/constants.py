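"""Shared vocabulary: strategy probes, networks, conditions, composites.

The 16 strategy probes form the response-strategies scale (RSS), a 1-7 Likert
battery administered after every trial question. Probes 1-13 share a none/a-lot
anchor; Difficulty, Facts and Specificity carry bespoke anchors and are the
three probes conventionally dropped from pattern visualisation.
"""

from __future__ import annotations

# Order matters: it is the canonical row order of every strategy matrix.
STRATEGIES: tuple[str, ...] = (
    "Significance",
    "Pers_Feelings",
    "Emotions",
    "Pers_Past_Exper",
    "Sequence_Events",
    "Loc_Obj_Places",
    "Loc_People",
    "Others_Feelings",
    "Moral_Principles",
    "Relationships",
    "Others_Personality",
    "Visual_Imagery",
    "Recent_Thoughts",
    "Difficulty",
    "Facts",
    "Specificity",
)

#: Probes rendered in pattern-QC plots (all but the three bespoke-anchor probes).
VISUALIZED_STRATEGIES: tuple[str, ...] = tuple(
    s for s in STRATEGIES if s not in ("Difficulty", "Facts", "Specificity")
)

RATING_MIN, RATING_MAX = 1, 7

NETWORKS: tuple[str, ...] = ("DN-A", "DN-B", "LANG", "FPN-A", "FPN-B", "CING-OPER")

FACTORS: tuple[str, ...] = (
    "Difficulty",
    "Autobiographical",
    "SceneConstruction",
    "OthersRelevant",
    "SelfRelevant",
)

CONDITIONS: tuple[str, ...] = (
    "Past Self",
    "Future Self",
    "Present Self",
    "Past Non-Self",
    "Future Non-Self",
    "Present Non-Self",
)

#: Conditions built to minimise episodic-projection demands.
CONTROL_CONDITIONS: frozenset[str] = frozenset(
    {"Present Self", "Past Non-Self", "Future Non-Self"}
)

#: Canonical composite memberships (overridable wherever composites are consumed).
CANONICAL_COMPOSITES: dict[str, tuple[str, ...]] = {
    "Difficulty": ("Facts", "Difficulty"),
    "Autobiographical": ("Pers_Past_Exper", "Sequence_Events"),
    "SceneConstruction": ("Visual_Imagery", "Loc_Obj_Places"),
    "OthersRelevant": ("Others_Feelings", "Others_Personality"),
    "SelfRelevant": ("Significance", "Pers_Feelings", "Emotions", "Recent_Thoughts"),
}

#: Probes excluded from all composites (inconsistent or weak between experiments).
CANONICAL_EXCLUSIONS: tuple[str, ...] = (
    "Relationships",
    "Specificity",
    "Moral_Principles",
    "Loc_People",
)
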