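"""The closed vocabulary of 19 standard anatomical airway sites.

The conducting-airway measurement set runs from the trachea to selected
segmental bronchi, plus five subsegmental path averages (the ``s``-prefixed
labels): trachea, right/left mainstem, bronchus intermedius, the five lobar
bronchi, five segmental bronchi (RB1, RB4, RB10, LB1, LB10) and the average
lumen diameter of the subsegments along each of those five segmental paths.
"""

from __future__ import annotations

from .errors import SiteVocabularyError

AIRWAY_SITES: tuple[str, ...] = (
    "TRACHEA",
    "RMB",
    "LMB",
    "BRONINT",
    "RUL",
    "RML",
    "RLL",
    "LUL",
    "LLL",
    "RB1",
    "RB4",
    "RB10",
    "LB1",
    "LB10",
    "sRB1",
    "sRB4",
    "sRB10",
    "sLB1",
    "sLB10",
)

#: Subsegmental path-average sites (the rest are single airways).
SUBSEGMENTAL_SITES: frozenset[str] = frozenset(
    {"sRB1", "sRB4", "sRB10", "sLB1", "sLB10"}
)

N_SITES: int = len(AIRWAY_SITES)

_SITE_SET = frozenset(AIRWAY_SITES)

SEXES: tuple[str, str] = ("female", "male")


def validate_site(label: str) -> str:
    """Return ``label`` if it belongs to the closed site vocabulary.

    Raises
    ------
    SiteVocabularyError
        For any label outside the 19-site set (matching is case-sensitive:
        the subsegmental sites are lower-case ``s`` + upper-case path).
    """
    if label not in _SITE_SET:
        raise SiteVocabularyError(
            f"unknown airway site {label!r}; expected one of {AIRWAY_SITES}"
        )
    return label


def is_subsegmental(label: str) -> bool:
    """True for the five subsegmental path-average sites."""
    return validate_site(label) in SUBSEGMENTAL_SITES
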