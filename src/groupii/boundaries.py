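"""Intron boundary profiles and window scanning.

Group II intron termini carry short class-specific consensus sequences
(generic 5' GUGYG ... AY 3'; e.g. the class C expansion GUNYGCCNRGCAUGG /
CCUACYCGAU). A per-class, per-side profile holds one emission distribution
per aligned column. Scanning scores every window offset with two algorithms
over the same parameterization:

* scorer A — best-path (Viterbi-style) log-odds of a glocal profile match
  allowing a small number of insertions/deletions;
* scorer B — sum-over-paths (Forward-style) log-odds over the same paths.

Because scorer B sums odds over a path set that includes scorer A's best
path, B >= A at every offset before calibration. Each scorer is z-scored
against its own random-sequence background, and the best calibrated score
is kept, so the two scorers are comparable where each works better.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import SequenceWindow

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: Emission log-odds assigned to ambiguous (non-ACGT) bases: a flat mismatch.
AMBIGUOUS_LOG_ODDS = -2.0

#: Path weights shared by both scorers: log-probability of advancing by a
#: match step vs. paying for an insertion or deletion step.
MATCH_LOG = math.log(0.90)
GAP_LOG = math.log(0.05)

#: Maximum drift (insertions minus deletions) allowed in a profile match.
DRIFT_SLACK = 3

TIER_THRESHOLDS = {"high": 6.0, "medium": 4.0, "low": 2.5}
_TIER_ORDER = {"high": 3, "medium": 2, "low": 1}


class Side(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


def tier_for(z: float, thresholds: dict[str, float] = TIER_THRESHOLDS) -> Optional[str]:
    if z >= thresholds["high"]:
        return "high"
    if z >= thresholds["medium"]:
        return "medium"
    if z >= thresholds["low"]:
        return "low"
    return None


@dataclass
class BoundaryProfile:
    """Per-column emission profile for one class and one intron side."""

    class_label: str
    side: Side
    #: (L, 4) per-column probabilities over A,C,G,T (each row sums to 1).
    emissions: np.ndarray
    trained_n: int
    #: background calibration per scorer: {"a": (mean, sd), "b": (mean, sd)}
    calibration: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.trained_n < 2:
            raise ValueError("a profile needs at least 2 training sequences")
        if not np.allclose(self.emissions.sum(axis=1), 1.0):
            raise ValueError("emission rows must sum to 1")

    def __len__(self) -> int:
        return self.emissions.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.emissions / 0.25)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.emissions.argmax(axis=1))

    def column_entropy(self) -> np.ndarray:
        p = self.emissions
        return -(p * np.log2(p)).sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "class_label": self.class_label,
            "side": self.side.value,
            "emissions": self.emissions.tolist(),
            "trained_n": self.trained_n,
            "calibration": {k: list(v) for k, v in self.calibration.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoundaryProfile":
        return cls(
            class_label=d["class_label"],
            side=Side(d["side"]),
            emissions=np.array(d["emissions"]),
            trained_n=int(d["trained_n"]),
            calibration={k: tuple(v) for k, v in d["calibration"].items()},
        )


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, 4) for c in seq.upper()], dtype=np.int64)


def _emission_rows(log_odds: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """(L, W) emission log-odds of each profile column at each window
    position; ambiguous bases get a flat mismatch."""
    lo = np.concatenate(
        [log_odds, np.full((log_odds.shape[0], 1), AMBIGUOUS_LOG_ODDS)], axis=1
    )
    return lo[:, encoded]


def _profile_scan(
    log_odds: np.ndarray, encoded: np.ndarray, slack: int = DRIFT_SLACK
) -> tuple[np.ndarray, np.ndarray]:
    """Score every offset with both scorers.

    Returns (viterbi_scores, forward_scores), each of length
    ``W - L + 1`` (empty when the window is shorter than the profile). The
    dynamic program runs over states (profile column, drift) and is
    vectorized across offsets; scorer A combines paths with max, scorer B
    with log-sum-exp, over identical path weights.
    """
    L = log_odds.shape[0]
    W = encoded.shape[0]
    n_off = W - L + 1
    if n_off <= 0:
        return np.empty(0), np.empty(0)
    E = _emission_rows(log_odds, encoded)  # (L, W)
    D = 2 * slack + 1
    NEG = -1e30
    # pad emissions so that index (i-1+d) is always valid
    pad = np.full((L, slack), NEG / 2)
    Epad = np.concatenate([pad, E, pad], axis=1)  # column p -> Epad[:, p+slack]

    def run(reduce_max: bool) -> np.ndarray:
        V = np.full((D, n_off), NEG)
        V[slack] = 0.0  # drift 0 before consuming any column
        for i in range(1, L + 1):
            new = np.full((D, n_off), NEG)
            for di, d in enumerate(range(-slack, slack + 1)):
                # match: consume column i at window pos o + (i-1) + d
                start = (i - 1) + d + slack
                em = Epad[i - 1, start : start + n_off]
                match = V[di] + MATCH_LOG + em
                # delete column i (no window consumed): drift decreases
                if di + 1 < D:
                    dele = V[di + 1] + GAP_LOG
                    if reduce_max:
                        new[di] = np.maximum(match, dele)
                    else:
                        new[di] = np.logaddexp(match, dele)
                else:
                    new[di] = match
            # insertions within level i: consume window base, drift increases
            for di in range(1, D):
                ins = new[di - 1] + GAP_LOG
                if reduce_max:
                    new[di] = np.maximum(new[di], ins)
                else:
                    new[di] = np.logaddexp(new[di], ins)
            V = new
        if reduce_max:
            return V.max(axis=0)
        out = V[0].copy()
        for di in range(1, D):
            out = np.logaddexp(out, V[di])
        return out

    return run(True), run(False)


def _calibration_seed(class_label: str, side: Side) -> int:
    return zlib.crc32(f"{class_label}:{side.value}".encode()) & 0x7FFFFFFF


def build_profile(
    training_windows: Sequence[str],
    class_label: str,
    side: Side,
    pseudocount: float = 1.0,
    n_calibration: int = 1000,
    seed: Optional[int] = None,
) -> BoundaryProfile:
    """Build an emission profile from aligned equal-length training blocks
    and calibrate both scorers against random background windows.

    Per-column base counts get a Laplace pseudocount. The calibration RNG
    seed is derived deterministically from the class and side unless given.
    """
    if len(training_windows) < 2:
        raise ValueError("need at least 2 training sequences")
    lengths = {len(s) for s in training_windows}
    if len(lengths) != 1:
        raise ValueError("ragged training alignment")
    L = lengths.pop()
    if L == 0:
        raise ValueError("empty training sequences")
    counts = np.full((L, 4), float(pseudocount))
    for s in training_windows:
        for i, c in enumerate(s.upper()):
            if c in _BASE_INDEX:
                counts[i, _BASE_INDEX[c]] += 1
    emissions = counts / counts.sum(axis=1, keepdims=True)
    profile = BoundaryProfile(
        class_label=class_label,
        side=side,
        emissions=emissions,
        trained_n=len(training_windows),
    )
    rng = np.random.default_rng(
        _calibration_seed(class_label, side) if seed is None else seed
    )
    lo = profile.log_odds
    scores_a = np.empty(n_calibration)
    scores_b = np.empty(n_calibration)
    for k in range(n_calibration):
        enc = rng.integers(0, 4, size=L)
        a, b = _profile_scan(lo, enc)
        scores_a[k], scores_b[k] = a[0], b[0]
    profile.calibration = {
        "a": (float(scores_a.mean()), float(max(scores_a.std(), 1e-6))),
        "b": (float(scores_b.mean()), float(max(scores_b.std(), 1e-6))),
    }
    return profile


@dataclass
class BoundaryCandidate:
    side: Side
    #: nt coordinate in the window of the intron's first (5') or last (3')
    #: nucleotide.
    window_position: int
    score_a: float
    score_b: float
    tier: str
    source_class: str = ""

    @property
    def best_score(self) -> float:
        return max(self.score_a, self.score_b)


class BoundaryBin(str, Enum):
    BOTH = "both"
    FIVE_ONLY = "five_only"
    THREE_ONLY = "three_only"
    NONE = "none"


@dataclass
class BoundaryCall:
    bin: BoundaryBin
    tier: Optional[str]
    candidates_5: list[BoundaryCandidate]
    candidates_3: list[BoundaryCandidate]


def _ungapped_scores(log_odds: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Plain per-offset log-odds sums (no drift), used to anchor the exact
    boundary position near a gapped-scan peak."""
    L = log_odds.shape[0]
    n_off = encoded.shape[0] - L + 1
    if n_off <= 0:
        return np.empty(0)
    E = _emission_rows(log_odds, encoded)
    out = np.zeros(n_off)
    for i in range(L):
        out += E[i, i : i + n_off]
    return out


def _side_candidates(
    window_seq: str,
    profile: BoundaryProfile,
    thresholds: dict[str, float],
    max_candidates: int,
) -> list[BoundaryCandidate]:
    enc = _encode(window_seq)
    va, vb = _profile_scan(profile.log_odds, enc)
    if va.size == 0:
        return []
    ma, sa = profile.calibration["a"]
    mb, sb = profile.calibration["b"]
    za = (va - ma) / sa
    zb = (vb - mb) / sb
    best = np.maximum(za, zb)
    ungapped = _ungapped_scores(profile.log_odds, enc)
    order = np.argsort(-best, kind="stable")
    kept: list[int] = []
    min_sep = len(profile)
    for o in order:
        if best[o] < thresholds["low"]:
            break
        if all(abs(o - k) >= min_sep for k in kept):
            kept.append(int(o))
        if len(kept) >= max_candidates:
            break
    out = []
    for o in kept:
        # a gapped peak can sit an offset or two off the motif when the best
        # path opens with an indel; re-anchor on the local ungapped argmax
        lo_off = max(0, o - DRIFT_SLACK)
        hi_off = min(len(ungapped), o + DRIFT_SLACK + 1)
        o_anchor = lo_off + int(np.argmax(ungapped[lo_off:hi_off]))
        pos = (
            o_anchor
            if profile.side is Side.FIVE_PRIME
            else o_anchor + len(profile) - 1
        )
        out.append(
            BoundaryCandidate(
                side=profile.side,
                window_position=pos,
                score_a=float(za[o]),
                score_b=float(zb[o]),
                tier=tier_for(float(best[o]), thresholds),
                source_class=profile.class_label,
            )
        )
    return out


def _merge_candidates(
    lists: Iterable[list[BoundaryCandidate]], min_sep: int
) -> list[BoundaryCandidate]:
    pool = sorted(
        (c for lst in lists for c in lst),
        key=lambda c: (-c.best_score, c.window_position, c.source_class),
    )
    kept: list[BoundaryCandidate] = []
    for c in pool:
        if all(abs(c.window_position - k.window_position) >= min_sep for k in kept):
            kept.append(c)
    return kept


def scan_boundaries(
    window: SequenceWindow | str,
    profile_5: BoundaryProfile | Sequence[BoundaryProfile],
    profile_3: BoundaryProfile | Sequence[BoundaryProfile],
    thresholds: dict[str, float] = TIER_THRESHOLDS,
    max_candidates: int = 8,
) -> BoundaryCall:
    """Scan a window for 5' and 3' boundary candidates.

    Passing a sequence of profiles per side scans a candidate with the
    profiles of several classes (used for unclassified/undefined
    candidates) and merges the ranked candidates.
    """
    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    p5s = [profile_5] if isinstance(profile_5, BoundaryProfile) else list(profile_5)
    p3s = [profile_3] if isinstance(profile_3, BoundaryProfile) else list(profile_3)
    c5 = _merge_candidates(
        ([_side_candidates(seq, p, thresholds, max_candidates) for p in p5s]),
        min_sep=min(len(p) for p in p5s),
    )
    c3 = _merge_candidates(
        ([_side_candidates(seq, p, thresholds, max_candidates) for p in p3s]),
        min_sep=min(len(p) for p in p3s),
    )
    if c5 and c3:
        bin_ = BoundaryBin.BOTH
        tier = min(
            c5[0].tier, c3[0].tier, key=lambda t: _TIER_ORDER[t]
        )
    elif c5:
        bin_, tier = BoundaryBin.FIVE_ONLY, c5[0].tier
    elif c3:
        bin_, tier = BoundaryBin.THREE_ONLY, c3[0].tier
    else:
        bin_, tier = BoundaryBin.NONE, None
    return BoundaryCall(bin=bin_, tier=tier, candidates_5=c5, candidates_3=c3)


class IntronStatus(str, Enum):
    HAVE_BOUNDARIES = "have_boundaries"
    AMBIGUOUS = "ambiguous"


@dataclass
class IntronCall:
    status: IntronStatus
    start_5: Optional[int] = None
    end_3: Optional[int] = None
    intron_seq: str = ""
    exon_context_5: str = ""
    exon_context_3: str = ""
    reasons: list[str] = field(default_factory=list)
    tier: Optional[str] = None


def _admit(
    candidates: list[BoundaryCandidate],
    tier_minimum: str,
    admit_single_submaximal: bool,
    position_ok,
) -> list[BoundaryCandidate]:
    valid = [c for c in candidates if position_ok(c.window_position)]
    admitted = [c for c in valid if _TIER_ORDER[c.tier] >= _TIER_ORDER[tier_minimum]]
    if not admitted and admit_single_submaximal and valid:
        # recall fallback: admit the single best lower-tier match
        admitted = [max(valid, key=lambda c: c.best_score)]
    return admitted


def resolve_boundaries(
    call: BoundaryCall,
    orf_span: tuple[int, int],
    length_bounds: tuple[int, int] = (400, 8000),
    tier_minimum: str = "high",
    admit_single_submaximal: bool = False,
) -> IntronCall:
    """Resolve a unique boundary pair, or declare the candidate ambiguous.

    A plausible 5' candidate lies upstream of the ORF and a plausible 3'
    candidate downstream; the pair must be in order and span a length within
    ``length_bounds`` (ORF strictly inside). The call succeeds only when
    exactly one plausible candidate remains on each side.
    """
    orf_start, orf_end = orf_span
    reasons: list[str] = []
    five = _admit(
        call.candidates_5,
        tier_minimum,
        admit_single_submaximal,
        lambda p: p < orf_start,
    )
    three = _admit(
        call.candidates_3,
        tier_minimum,
        admit_single_submaximal,
        lambda p: p >= orf_end,
    )
    lo, hi = length_bounds
    pairs = [
        (c5, c3)
        for c5 in five
        for c3 in three
        if c5.window_position < c3.window_position
        and lo <= c3.window_position - c5.window_position + 1 <= hi
    ]
    pos5 = sorted({c5.window_position for c5, _ in pairs})
    pos3 = sorted({c3.window_position for _, c3 in pairs})
    if len(pos5) == 1 and len(pos3) == 1:
        c5, c3 = pairs[0]
        tier = min(c5.tier, c3.tier, key=lambda t: _TIER_ORDER[t])
        return IntronCall(
            status=IntronStatus.HAVE_BOUNDARIES,
            start_5=pos5[0],
            end_3=pos3[0],
            tier=tier,
        )
    if not five:
        reasons.append("no_5_candidate")
    if not three:
        reasons.append("no_3_candidate")
    if five and three and not pairs:
        if all(
            c3.window_position <= c5.window_position for c5 in five for c3 in three
        ):
            reasons.append("order_violated")
        else:
            reasons.append("length_out_of_bounds")
    if len(pos5) > 1:
        reasons.append("multiple_5")
    if len(pos3) > 1:
        reasons.append("multiple_3")
    return IntronCall(status=IntronStatus.AMBIGUOUS, reasons=reasons)


def generate_intron(
    window: SequenceWindow | str,
    intron_call: IntronCall,
    context_nt: int = 20,
) -> IntronCall:
    """Fill in the intron sequence and exon context for a resolved call.

    The intron sequence is the exact window substring from the 5' boundary
    to the 3' boundary inclusive; output stays in the DNA alphabet (use
    :func:`as_rna` for the RNA view).
    """
    if intron_call.status is not IntronStatus.HAVE_BOUNDARIES:
        raise ValueError("can only generate a sequence for resolved boundaries")
    seq = window.window_seq if isinstance(window, SequenceWindow) else window
    s, e = intron_call.start_5, intron_call.end_3
    if s is None or e is None or s < 0 or e >= len(seq):
        raise ValueError("boundaries outside window")
    intron_call.intron_seq = seq[s : e + 1]
    intron_call.exon_context_5 = seq[max(0, s - context_nt) : s]
    intron_call.exon_context_3 = seq[e + 1 : e + 1 + context_nt]
    return intron_call


def as_rna(dna: str) -> str:
    return dna.replace("T", "U").replace("t", "u")
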