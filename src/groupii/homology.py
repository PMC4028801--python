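"""Translated local-alignment engine with Karlin-Altschul statistics.

Emulates offline the two database-search modes the pipeline needs:
a protein query against six-frame translated DNA (tblastn-like) and, by
symmetry, a DNA candidate against a protein reference set (blastx-like,
same engine with roles swapped). Alignment is exact affine-gap
Smith-Waterman (no heuristic seeding or banding); significance uses the
standard gapped Karlin-Altschul parameters for BLOSUM62 with gap cost
11 + k.

A fast-reject prescreen (bit-vector infix edit distance via edlib) can skip
frame/query pairs that cannot plausibly reach the E-value cutoff; it is on
by default and can be disabled for exhaustive searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

#: Fraction of the query length above which an infix edit distance is
#: considered hopeless. Unrelated protein/frame pairs sit near 0.76*m;
#: genuinely related pairs (>=55% identity over half the query or more)
#: stay below ~0.5*m.
PRESCREEN_FRACTION = 0.62

#: Genetic code used for all translations (bacterial/archaeal).
TRANSLATION_TABLE = 11


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs, and Karlin-Altschul parameters.

    A gap of length k costs ``gap_open + k * gap_extend``, matching the
    BLAST convention for its (11, 1) default. ``lam``/``K`` are the standard
    gapped BLOSUM62 values.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw_score)

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2)


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


DEFAULT_SCHEME = ScoringScheme()

_MATRIX_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize_protein(protein: str) -> str:
    """Map residues outside the matrix alphabet to X (universal mismatch)."""
    p = protein.upper()
    if all(c in _MATRIX_ALPHABET for c in p):
        return p
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in p)


@dataclass
class FrameTranslation:
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2 offset within the strand
    protein: str


def six_frame_translate(dna: str) -> list[FrameTranslation]:
    """All six reading frames (genetic code table 11), stops as '*',
    partial terminal codons dropped."""
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    frames = []
    seq = Seq(dna.upper())
    rc = seq.reverse_complement()
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            frames.append(
                FrameTranslation(strand, f, str(sub.translate(table=TRANSLATION_TABLE)))
            )
    return frames


@dataclass
class LocalAlignment:
    """Best-scoring local alignment between two proteins."""

    score: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    #: (query_pos, subject_pos) pairs; None marks a gap on that side.
    aligned_pairs: list[tuple[Optional[int], Optional[int]]]

    @property
    def length(self) -> int:
        return len(self.aligned_pairs)


def _pairs_from_alignment(aln) -> list[tuple[Optional[int], Optional[int]]]:
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    qblocks, sblocks = aln.aligned
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_q is not None:
            for q in range(prev_q, qs):
                pairs.append((q, None))
            for s in range(prev_s, ss):
                pairs.append((None, s))
        qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
        pairs.extend((qs + i, ss + i) for i in range(qe - qs))
        prev_q, prev_s = qe, se
    return pairs


def local_align(
    query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> Optional[LocalAlignment]:
    """Affine-gap Smith-Waterman optimum, or None if no positive score.

    Ties between co-optimal alignments are broken deterministically:
    prefer the longer alignment, then the smaller subject start, then the
    smaller query start (examining a bounded number of co-optima).
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q = _sanitize_protein(query)
    s = _sanitize_protein(subject)
    aligner = scheme.make_aligner()
    score = aligner.score(q, s)
    if score <= 0:
        return None
    alignments = aligner.align(q, s)
    best = None
    best_key = None
    for i, aln in enumerate(alignments):
        qb, sb = aln.aligned
        length = int(sum(qe - qs for qs, qe in qb))
        key = (-length, int(sb[0][0]), int(qb[0][0]))
        if best_key is None or key < best_key:
            best, best_key = aln, key
        if i >= 15:
            break
    qb, sb = best.aligned
    return LocalAlignment(
        score=int(round(best.score)),
        query_interval=(int(qb[0][0]), int(qb[-1][1])),
        subject_interval=(int(sb[0][0]), int(sb[-1][1])),
        aligned_pairs=_pairs_from_alignment(best),
    )


@dataclass
class HSP:
    """A high-scoring pair from a translated search.

    ``subject_interval`` is in nucleotides on the forward strand of the DNA
    that was searched; ``frame`` is the 0/1/2 offset within ``strand``.
    """

    query_id: str
    subject_accession: str
    subject_interval: tuple[int, int]
    strand: str
    frame: int
    raw_score: int
    bit_score: float
    evalue: float
    #: (query_pos, subject_codon_index) pairs, None marking gaps. The codon
    #: index is within the translated frame, not nucleotides.
    aligned_pairs: list[tuple[Optional[int], Optional[int]]] = field(repr=False, default_factory=list)
    has_internal_stop: bool = False
    #: query/subject residues of the aligned region (diagnostics).
    query_aa_interval: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        s, e = self.subject_interval
        if e <= s or e - s < 3:
            raise ValueError("HSP must span at least one codon")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _prescreen_pass(query: str, frame_protein: str, max_fraction: float) -> bool:
    if len(frame_protein) < 10:
        return False
    res = edlib.align(query, frame_protein, mode="HW", task="distance")
    return res["editDistance"] <= max_fraction * len(query)


def _frame_aa_to_nt(
    aa_start: int, aa_end: int, strand: str, frame: int, dna_len: int
) -> tuple[int, int]:
    """Convert an [aa_start, aa_end) interval in a frame translation to a
    forward-strand nucleotide interval."""
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == "+":
        return (nt_start, nt_end)
    return (dna_len - nt_end, dna_len - nt_start)


def translated_search(
    query_protein: str,
    dna: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    evalue_cutoff: float = 1e-20,
    query_id: str = "query",
    subject_accession: str = "subject",
    prescreen: bool = True,
    max_hsps_per_frame: int = 1,
) -> list[HSP]:
    """Search a protein against all six frames of a DNA sequence.

    E-values follow E = K*m*n*exp(-lambda*S) with m the query length and n
    the frame length in residues. HSPs with E <= cutoff are returned sorted
    by ascending E-value (ties by score, then coordinates).

    With ``max_hsps_per_frame`` > 1, additional non-overlapping HSPs per
    frame are recovered by masking the aligned subject residues and
    realigning; this is how repeated ORF copies (e.g. twintrons) and
    frameshift-split ORFs surface as multiple HSPs.
    """
    if len(dna) < 3:
        return []
    query = _sanitize_protein(query_protein)
    m = len(query)
    hsps: list[HSP] = []
    for ft in six_frame_translate(dna):
        protein = ft.protein
        n = len(protein)
        if n == 0:
            continue
        if prescreen and not _prescreen_pass(query, protein, PRESCREEN_FRACTION):
            continue
        working = protein
        for _ in range(max_hsps_per_frame):
            aln = local_align(query, working, scheme)
            if aln is None:
                break
            ev = scheme.evalue(aln.score, m, n)
            if ev > evalue_cutoff:
                break
            ss, se = aln.subject_interval
            segment = protein[ss:se]
            nt_interval = _frame_aa_to_nt(ss, se, ft.strand, ft.frame, len(dna))
            hsps.append(
                HSP(
                    query_id=query_id,
                    subject_accession=subject_accession,
                    subject_interval=nt_interval,
                    strand=ft.strand,
                    frame=ft.frame,
                    raw_score=aln.score,
                    bit_score=scheme.bit_score(aln.score),
                    evalue=ev,
                    aligned_pairs=aln.aligned_pairs,
                    has_internal_stop="*" in segment,
                    query_aa_interval=aln.query_interval,
                )
            )
            working = working[:ss] + "X" * (se - ss) + working[se:]
    hsps.sort(
        key=lambda h: (h.evalue, -h.raw_score, h.subject_interval, h.strand, h.frame)
    )
    return hsps


@dataclass
class CandidateLocus:
    """A unique candidate region pooled from overlapping HSPs."""

    accession: str
    interval: tuple[int, int]
    strand: str
    best_evalue: float
    supporting_queries: list[str]


def pool_hits(hsps: Iterable[HSP]) -> list[CandidateLocus]:
    """Merge HSPs into unique non-overlapping candidate loci.

    HSPs on the same (accession, strand) whose nucleotide intervals overlap
    by at least 1 nt are merged into one locus spanning their union;
    bookended (merely adjacent) intervals stay separate. Output is sorted by
    accession, then start.
    """
    by_key: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        by_key.setdefault((h.subject_accession, h.strand), []).append(h)
    loci: list[CandidateLocus] = []
    for (acc, strand), group in by_key.items():
        group.sort(key=lambda h: h.subject_interval)
        current: list[HSP] = []
        cur_start = cur_end = None
        def flush():
            if current:
                loci.append(
                    CandidateLocus(
                        accession=acc,
                        interval=(cur_start, cur_end),
                        strand=strand,
                        best_evalue=min(h.evalue for h in current),
                        supporting_queries=sorted({h.query_id for h in current}),
                    )
                )
        for h in group:
            s, e = h.subject_interval
            if cur_end is not None and s < cur_end:  # >=1 nt overlap
                cur_end = max(cur_end, e)
                current.append(h)
            else:
                flush()
                current = [h]
                cur_start, cur_end = s, e
        flush()
    loci.sort(key=lambda l: (l.accession, l.interval, l.strand))
    return loci


def hsps_to_tsv(hsps: Iterable[HSP]) -> str:
    """Tabular hit report (query, accession, start, end, strand, frame,
    score, bit score, evalue)."""
    lines = ["query\taccession\tstart\tend\tstrand\tframe\tscore\tbits\tevalue"]
    for h in hsps:
        s, e = h.subject_interval
        lines.append(
            f"{h.query_id}\t{h.subject_accession}\t{s}\t{e}\t{h.strand}\t"
            f"{h.frame}\t{h.raw_score}\t{h.bit_score:.1f}\t{h.evalue:.3g}"
        )
    return "\n".join(lines) + "\n"
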