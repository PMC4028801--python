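"""IEP domain inventory, ORF intactness, and protein assignment.

The IEP of a group II intron carries reverse-transcriptase subdomains
(0-7), the thumb domain X, and in some classes a C-terminal endonuclease
En. Rather than modelling whole domains, each reference IEP designates one
conserved residue per domain as a proxy: a candidate is judged to contain a
domain when the proxy's reference position falls inside an aligned
(non-gap) column of a candidate/reference alignment — the candidate residue
itself need not be identical.

Truncations show up as missing domains; twintrons and other multi-copy
arrangements as extra (duplicated) domains; frameshifts and premature stops
are caught later by requiring a single uninterrupted alignment against the
candidate's closest curated relative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .homology import (
    DEFAULT_SCHEME,
    HSP,
    ScoringScheme,
    TRANSLATION_TABLE,
    local_align,
    translated_search,
)
from .seqio import SequenceWindow


@dataclass
class ReferenceIEP:
    """A per-class reference protein with one proxy residue per domain."""

    class_label: str  # ML, CL1, CL2, A, B, C, D, E, F
    protein: str
    #: domain label -> 0-based position of the proxy residue.
    proxy_positions: dict[str, int]
    #: ordered domain labels expected for this class (En only where present).
    expected_domains: list[str]
    annotated_start_codon: str = "ATG"

    def __post_init__(self) -> None:
        positions = [self.proxy_positions[d] for d in self.expected_domains]
        if len(set(positions)) != len(positions) or positions != sorted(positions):
            raise ValueError("proxy positions must be unique and increasing")
        for d in self.expected_domains:
            if d not in self.proxy_positions:
                raise ValueError(f"domain {d} has no proxy position")

    @property
    def region(self) -> tuple[int, int]:
        """[start, end) span from domain 0's proxy to domain X's proxy."""
        return (self.proxy_positions["0"], self.proxy_positions["X"] + 1)


class DomainCategory(str, Enum):
    NORMAL = "normal"
    MISSING = "missing"
    EXTRA = "extra"
    MISSING_AND_EXTRA = "missing_and_extra"


@dataclass
class DomainInventory:
    counts: dict[str, int]
    category: DomainCategory
    hsp_count: int = 0


def categorize_counts(counts: dict[str, int]) -> DomainCategory:
    """Total, mutually exclusive mapping from domain counts to category."""
    missing = any(c == 0 for c in counts.values())
    extra = any(c > 1 for c in counts.values())
    if missing and extra:
        return DomainCategory.MISSING_AND_EXTRA
    if missing:
        return DomainCategory.MISSING
    if extra:
        return DomainCategory.EXTRA
    return DomainCategory.NORMAL


def _collect_hsps(
    query_protein: str,
    window_seq: str,
    scheme: ScoringScheme,
    evalue_cutoff: float,
    prescreen: bool,
) -> list[HSP]:
    return translated_search(
        query_protein,
        window_seq,
        scheme,
        evalue_cutoff=evalue_cutoff,
        prescreen=prescreen,
        max_hsps_per_frame=3,
    )


def domain_inventory(
    window: SequenceWindow | str,
    reference: ReferenceIEP,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_cutoff: float = 1e-20,
    prescreen: bool = True,
) -> DomainInventory:
    """Count each expected domain once per alignment whose aligned columns
    cover the domain's proxy position.

    Counts above one arise from repeated alignments to distinct window
    segments (the search masks each aligned segment and realigns), as in
    twintrons.
    """
    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    hsps = _collect_hsps(reference.protein, seq, scheme, evalue_cutoff, prescreen)
    counts = {d: 0 for d in reference.expected_domains}
    for hsp in hsps:
        covered = {q for q, s in hsp.aligned_pairs if q is not None and s is not None}
        for d in reference.expected_domains:
            if reference.proxy_positions[d] in covered:
                counts[d] += 1
    return DomainInventory(
        counts=counts, category=categorize_counts(counts), hsp_count=len(hsps)
    )


def pick_reference(
    references: Sequence[ReferenceIEP],
    intron_class: str,
    window: SequenceWindow | str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    prescreen: bool = True,
) -> ReferenceIEP:
    """Choose the reference IEP for a candidate's class.

    CL candidates take CL1 or CL2 by better total alignment score;
    undefined/unclassified candidates take the best-scoring reference
    overall.
    """
    if intron_class == "CL":
        pool = [r for r in references if r.class_label in ("CL1", "CL2")]
    elif intron_class in ("undefined", "unclassified"):
        pool = list(references)
    else:
        pool = [r for r in references if r.class_label == intron_class]
    if not pool:
        raise ValueError(f"no reference IEP for class {intron_class!r}")
    if len(pool) == 1:
        return pool[0]
    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    scored = []
    for ref in pool:
        hsps = translated_search(
            ref.protein, seq, scheme, evalue_cutoff=10.0, prescreen=prescreen
        )
        best = hsps[0].raw_score if hsps else 0
        scored.append((-best, ref.class_label, ref))
    scored.sort(key=lambda t: t[:2])
    return scored[0][2]


class OrfIssue(str, Enum):
    PREMATURE_STOP = "premature_stop"
    GAP_INSERTION = "gap_insertion"
    MULTIPLE_HSPS = "multiple_hsps"
    LOW_COVERAGE = "low_coverage"


@dataclass
class OrfStatus:
    intact: bool
    issues: list[OrfIssue]
    hsp_count: int


def _max_gap_run(pairs, side: int) -> int:
    longest = run = 0
    for pair in pairs:
        if pair[side] is None:
            run += 1
            longest = max(longest, run)
        else:
            run = 0
    return longest


def orf_intactness(
    window: SequenceWindow | str,
    relative_protein: str,
    relative_region: tuple[int, int],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_cutoff: float = 1e-20,
    gap_allowance_codons: int = 2,
    coverage_fraction: float = 0.95,
    prescreen: bool = True,
) -> OrfStatus:
    """Judge ORF intactness from the alignment against the closest curated
    relative.

    Intact requires a single HSP, no stop codon inside the candidate's
    aligned frame, no gap run longer than ``gap_allowance_codons`` on either
    sequence, and coverage of at least ``coverage_fraction`` of the
    relative's domain 0->X span.
    """
    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    hsps = _collect_hsps(relative_protein, seq, scheme, evalue_cutoff, prescreen)
    issues: list[OrfIssue] = []
    if not hsps:
        return OrfStatus(intact=False, issues=[OrfIssue.LOW_COVERAGE], hsp_count=0)
    if len(hsps) > 1:
        issues.append(OrfIssue.MULTIPLE_HSPS)
    best = hsps[0]
    if best.has_internal_stop:
        issues.append(OrfIssue.PREMATURE_STOP)
    gap_run = max(_max_gap_run(best.aligned_pairs, 0), _max_gap_run(best.aligned_pairs, 1))
    if gap_run > gap_allowance_codons:
        issues.append(OrfIssue.GAP_INSERTION)
    r_start, r_end = relative_region
    span = max(1, r_end - r_start)
    covered = sum(
        1
        for q, s in best.aligned_pairs
        if q is not None and s is not None and r_start <= q < r_end
    )
    if covered / span < coverage_fraction:
        issues.append(OrfIssue.LOW_COVERAGE)
    return OrfStatus(intact=not issues, issues=issues, hsp_count=len(hsps))


START_CODONS = ("ATG", "GTG", "TTG")

#: Shine-Dalgarno position weight matrix for the AGGAGG core: log2 odds with
#: consensus probability 0.85 against a uniform background.
_SD_CONSENSUS = "AGGAGG"
_BASES = "ACGT"
SD_PWM = np.full((len(_SD_CONSENSUS), 4), math.log2(0.05 / 0.25))
for _i, _b in enumerate(_SD_CONSENSUS):
    SD_PWM[_i, _BASES.index(_b)] = math.log2(0.85 / 0.25)


def sd_motif_score(
    window_seq: str,
    start_pos: int,
    spacer_range: tuple[int, int] = (5, 13),
) -> float:
    """Best Shine-Dalgarno PWM score in the allowed spacer range upstream of
    a putative start codon, floored at 0 (absence of a motif is neutral)."""
    best = 0.0
    width = SD_PWM.shape[0]
    for spacer in range(spacer_range[0], spacer_range[1] + 1):
        s = start_pos - spacer - width
        if s < 0:
            continue
        segment = window_seq[s : s + width]
        if len(segment) < width or any(c not in _BASES for c in segment):
            continue
        score = sum(SD_PWM[i, _BASES.index(c)] for i, c in enumerate(segment))
        best = max(best, score)
    return best


@dataclass
class IEPSequence:
    protein: str
    start_codon: str
    start_pos_window: int
    sd_score: float

    def __post_init__(self) -> None:
        if not self.protein.startswith("M"):
            raise ValueError("IEP protein must begin with M")
        if self.start_codon not in START_CODONS:
            raise ValueError(f"bad start codon {self.start_codon!r}")


def assign_iep(
    window: SequenceWindow | str,
    relative_protein: str,
    relative_start_codon: str = "ATG",
    scheme: ScoringScheme = DEFAULT_SCHEME,
    scan_halfwidth_nt: int = 45,
    spacer_range: tuple[int, int] = (5, 13),
    codon_match_bonus: float = 2.0,
    distance_penalty_per_codon: float = 0.5,
    prescreen: bool = True,
) -> Optional[IEPSequence]:
    """Choose the IEP start codon and emit the protein sequence.

    Start candidates (ATG/GTG/TTG, in frame) are scanned within
    ``scan_halfwidth_nt`` of the window position that aligns to the
    relative's start; each is scored as an alignment-consistency term
    (penalizing displacement), a bonus for matching the relative's
    annotated start codon, and the Shine-Dalgarno motif score of its
    upstream spacer. Returns None when no start codon lies in the scan
    range (the candidate is flagged by the caller).
    """
    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    hsps = translated_search(
        relative_protein, seq, scheme, evalue_cutoff=1e-10, prescreen=prescreen
    )
    forward = [h for h in hsps if h.strand == "+"]
    if not forward:
        return None
    best = forward[0]
    anchor = next(
        ((q, s) for q, s in best.aligned_pairs if q is not None and s is not None),
        None,
    )
    if anchor is None:
        return None
    q0, s0 = anchor
    est = best.frame + 3 * (s0 - q0)  # window nt aligning to relative aa 0
    if est < 0 or est > len(seq) - 3:
        return None
    candidates = []
    half_codons = scan_halfwidth_nt // 3
    for k in range(-half_codons, half_codons + 1):
        p = est + 3 * k
        if p < 0 or p + 3 > len(seq):
            continue
        codon = seq[p : p + 3]
        if codon not in START_CODONS:
            continue
        score = (
            -distance_penalty_per_codon * abs(k)
            + (codon_match_bonus if codon == relative_start_codon else 0.0)
            + sd_motif_score(seq, p, spacer_range)
        )
        candidates.append((-score, abs(k), p, codon))
    if not candidates:
        return None
    candidates.sort()
    neg_score, _, p, codon = candidates[0]
    coding = seq[p : p + 3 * ((len(seq) - p) // 3)]
    protein = str(Seq(coding).translate(table=TRANSLATION_TABLE))
    stop = protein.find("*")
    if stop >= 0:
        protein = protein[:stop]
    if not protein:
        return None
    protein = "M" + protein[1:]
    sd = sd_motif_score(seq, p, spacer_range)
    return IEPSequence(
        protein=protein, start_codon=codon, start_pos_window=p, sd_score=sd
    )


def candidate_region(
    candidate_protein: str,
    reference: ReferenceIEP,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[int, int]:
    """Map the reference's domain 0->X span onto candidate protein
    coordinates via a pairwise alignment (used to excise the region compared
    during redundancy grouping)."""
    aln = local_align(reference.protein, candidate_protein, scheme)
    if aln is None:
        return (0, len(candidate_protein))
    r_start, r_end = reference.region
    pairs = [(q, s) for q, s in aln.aligned_pairs if q is not None and s is not None]
    start = next((s for q, s in pairs if q >= r_start), pairs[0][1])
    end = next((s for q, s in reversed(pairs) if q < r_end), pairs[-1][1])
    if end < start:
        start, end = end, start
    return (start, end + 1)
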