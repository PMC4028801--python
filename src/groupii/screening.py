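"""Screening candidates: non-group-II RT removal and intron class assignment.

Group II intron IEPs share their reverse-transcriptase core with other
bacterial retroelements (retrons, diversity-generating retroelements,
CRISPR-associated RTs), so a homology hit alone does not make a candidate a
group II intron. Both screens rank a candidate's matches against a reference
set and apply a top-three counting rule:

* RT verdict — candidates whose top three matches in a categorized RT
  database are all group II introns are "probable"; one or two of three,
  "possible"; none, "non_group_II". Only probable candidates proceed by
  default.
* Class assignment — if the top three matches in the curated intron set
  share one defined class the candidate takes that class; if all three are
  curated "unclassified" introns it is "unclassified"; any mixture is
  "undefined".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .homology import DEFAULT_SCHEME, ScoringScheme, translated_search
from .seqio import SequenceWindow

#: The eight phylogenetic lineages of group II intron IEPs.
DEFINED_CLASSES = ("ML", "CL", "A", "B", "C", "D", "E", "F")

#: Closed registry of RT categories for the reference database.
RT_CATEGORIES = (
    "group_II",
    "retron",
    "DGR",
    "CRISPR_RT",
    "abi_RT",
    "other_RT",
)


def normalize_class(label: str) -> str:
    """Collapse reference subclasses onto the eight assignment classes
    (CL1/CL2 -> CL); 'unclassified' passes through."""
    if label in ("CL1", "CL2"):
        return "CL"
    return label


@dataclass
class RTReference:
    id: str
    sequence: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in RT_CATEGORIES:
            raise ValueError(f"unknown RT category {self.category!r}")


class RTVerdictValue(str, Enum):
    PROBABLE = "probable"
    POSSIBLE = "possible"
    NON_GROUP_II = "non_group_II"


@dataclass
class RTVerdict:
    value: RTVerdictValue
    #: (reference id, category, evalue) of the ranked top matches (<= 3).
    top_matches: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class ClassAssignment:
    intron_class: str  # ML/CL/A..F, "unclassified", or "undefined"
    closest_relative_id: Optional[str]
    top_matches: list[tuple[str, str, float]] = field(default_factory=list)


def _ranked_matches(
    window_seq: str,
    references: Sequence,
    scheme: ScoringScheme,
    evalue_cutoff: float,
    prescreen: bool,
) -> list[tuple[object, float, int]]:
    """Best hit per reference (ref, evalue, score), ranked by E-value, then
    raw score, then reference id — a deterministic order independent of
    database input order."""
    hits = []
    for ref in references:
        hsps = translated_search(
            ref.sequence,
            window_seq,
            scheme,
            evalue_cutoff=evalue_cutoff,
            query_id=ref.id,
            prescreen=prescreen,
        )
        if hsps:
            best = hsps[0]
            hits.append((ref, best.evalue, best.raw_score))
    hits.sort(key=lambda t: (t[1], -t[2], t[0].id))
    return hits


def rt_verdict(
    window: SequenceWindow | str,
    rt_db: Sequence[RTReference],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_cutoff: float = 1e-20,
    probable_votes: int = 3,
    prescreen: bool = True,
) -> RTVerdict:
    """Classify a candidate window by the categories of its top three RT
    database matches.

    ``probable_votes`` adjusts the stringency of the counting rule (3 by
    default: all three top matches must be group II introns). With fewer
    than three references hit, the rule applies to the available ranks, so a
    "probable" verdict cannot be reached with fewer hits than
    ``probable_votes``.
    """
    if not rt_db:
        raise ValueError("RT reference database is empty")
    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    ranked = _ranked_matches(seq, rt_db, scheme, evalue_cutoff, prescreen)
    top = ranked[:3]
    matches = [(ref.id, ref.category, ev) for ref, ev, _ in top]
    n_gii = sum(1 for _, cat, _ in matches if cat == "group_II")
    if n_gii >= probable_votes and len(top) >= probable_votes:
        value = RTVerdictValue.PROBABLE
    elif n_gii >= 1:
        value = RTVerdictValue.POSSIBLE
    else:
        value = RTVerdictValue.NON_GROUP_II
    return RTVerdict(value=value, top_matches=matches)


def assign_class(
    window: SequenceWindow | str,
    curated_db: Sequence,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_cutoff: float = 1e-20,
    prescreen: bool = True,
) -> ClassAssignment:
    """Assign an intron class from the top three curated-set matches.

    ``curated_db`` entries need ``id``, ``sequence``/``protein`` and
    ``class_label`` attributes. Zero hits yields "undefined" with a null
    closest relative (the candidate is flagged and set aside by the
    pipeline).
    """

    class _Wrap:
        def __init__(self, entry):
            self.entry = entry
            self.id = entry.id
            self.sequence = getattr(entry, "sequence", None) or entry.protein
            self.class_label = entry.class_label

    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    wrapped = [_Wrap(e) for e in curated_db]
    ranked = _ranked_matches(seq, wrapped, scheme, evalue_cutoff, prescreen)
    top = ranked[:3]
    matches = [(ref.id, ref.class_label, ev) for ref, ev, _ in top]
    if not top:
        return ClassAssignment("undefined", None, [])
    closest = top[0][0].id
    labels = {normalize_class(ref.class_label) for ref, _, _ in top}
    if len(top) == 3 and len(labels) == 1:
        label = labels.pop()
        if label in DEFINED_CLASSES:
            return ClassAssignment(label, closest, matches)
        if label == "unclassified":
            return ClassAssignment("unclassified", closest, matches)
    return ClassAssignment("undefined", closest, matches)
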