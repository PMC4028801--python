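"""Redundancy reduction: >=95%-identity grouping and prototype selection.

Mobile introns leave many identical or near-identical copies across genomes
and database entries. To reduce the redundancy, the IEPs of one class are
aligned over the region spanning RT domain 0 through the thumb domain X,
pairwise maximum-likelihood distances are computed under the JTT model, and
candidates less than 0.061 substitutions/site apart (about 95% identity
under JTT) are joined into one group by single linkage. Each group gets one
prototype — and one prototype per distinct species in the group, so a
redundant intron from a different species is still reported as unique.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import _jtt
from .seqio import read_fasta, write_fasta

#: Distance below which two IEPs fall in the same ~95%-identity group.
DEFAULT_DISTANCE_THRESHOLD = 0.061

_AA_INDEX = {a: i for i, a in enumerate(_jtt.AA_ORDER)}


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or (np.diag(self.d) != 0).any():
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.ids)]
        for i, name in enumerate(self.ids):
            lines.append(name + "\t" + "\t".join(f"{x:.6f}" for x in self.d[i]))
        return "\n".join(lines) + "\n"


@dataclass
class IdentityGroup:
    group_id: str
    class_label: str
    member_ids: list[str]
    #: (member_id, species) — the group representative plus one per species.
    prototypes: list[tuple[str, str]] = field(default_factory=list)
    dna_alignment: list[tuple[str, str]] = field(default_factory=list)


def align_orf_region(
    members: Sequence[tuple[str, str]],
    mafft_path: Optional[str] = None,
) -> list[tuple[str, str]]:
    """Progressive multiple alignment of excised domain 0->X regions.

    ``members`` are (id, region_protein) pairs — callers excise the region
    before alignment so columns outside domains 0->X never enter the
    distance computation. Alignment is delegated to MAFFT; a single member
    short-circuits to itself.
    """
    if len(members) == 0:
        return []
    if len(members) == 1:
        return [tuple(members[0])]
    exe = mafft_path or shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft executable not found on PATH")
    fasta = write_fasta(members)
    proc = subprocess.run(
        [exe, "--quiet", "--auto", "--amino", "-"],
        input=fasta.encode(),
        capture_output=True,
        check=True,
    )
    aligned = dict(read_fasta(proc.stdout.decode()))
    return [(name, aligned[name]) for name, _ in members]


def _pair_counts(a: str, b: str) -> np.ndarray:
    """20x20 residue-pair counts over comparable columns (gap or
    non-standard columns excluded pairwise)."""
    N = np.zeros((20, 20))
    for ca, cb in zip(a.upper(), b.upper()):
        ia = _AA_INDEX.get(ca)
        ib = _AA_INDEX.get(cb)
        if ia is not None and ib is not None:
            N[ia, ib] += 1
    return N


def ml_distance(a: str, b: str, t_max: float = 10.0) -> float:
    """Maximum-likelihood distance (substitutions/site) between two aligned
    proteins under the JTT model, by 1-D likelihood optimization.

    Raises ValueError when the sequences share no comparable columns.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    N = _pair_counts(a, b)
    total = N.sum()
    if total == 0:
        raise ValueError("no comparable columns")
    if N.trace() == total:
        return 0.0
    log_pi = np.log(_jtt.FREQUENCIES)

    def neg_loglik(t: float) -> float:
        P = _jtt.transition_matrix(t)
        return -float((N * (log_pi[:, None] + np.log(P))).sum())

    res = minimize_scalar(
        neg_loglik, bounds=(1e-8, t_max), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def distance_matrix(aligned: Sequence[tuple[str, str]]) -> DistanceMatrix:
    ids = [name for name, _ in aligned]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ml_distance(aligned[i][1], aligned[j][1])
    return DistanceMatrix(ids=ids, d=d)


def group_by_threshold(
    matrix: DistanceMatrix,
    threshold: float = DEFAULT_DISTANCE_THRESHOLD,
    class_label: str = "",
) -> list[IdentityGroup]:
    """Single-linkage connected components of the graph whose edges join
    pairs at distance strictly below ``threshold``; groups are ordered by
    their smallest member id."""
    n = len(matrix.ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if matrix.d[i, j] < threshold:
                parent[find(i)] = find(j)
    components: dict[int, list[str]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(matrix.ids[i])
    ordered = sorted(components.values(), key=lambda m: min(m))
    return [
        IdentityGroup(
            group_id=f"{class_label or 'G'}_{k:03d}",
            class_label=class_label,
            member_ids=sorted(members),
        )
        for k, members in enumerate(ordered)
    ]


def select_prototypes(
    group: IdentityGroup,
    species: dict[str, str],
    lengths: Optional[dict[str, int]] = None,
) -> list[tuple[str, str]]:
    """Choose the group's prototypes.

    The primary prototype is the longest intact member (ties broken by
    lexicographic id); additionally, each distinct species in the group is
    assigned a prototype by the same criterion. The result is stored on the
    group and returned.
    """
    if not group.member_ids:
        raise ValueError("empty group")
    lengths = lengths or {}

    def key(member: str) -> tuple[int, str]:
        return (-lengths.get(member, 0), member)

    primary = min(group.member_ids, key=key)
    chosen: dict[str, str] = {}
    for sp in sorted({species.get(m, "") for m in group.member_ids}):
        members = [m for m in group.member_ids if species.get(m, "") == sp]
        chosen[min(members, key=key)] = sp
    chosen.setdefault(primary, species.get(primary, ""))
    group.prototypes = sorted(chosen.items())
    return group.prototypes


def groups_to_tsv(groups: Sequence[IdentityGroup], species: dict[str, str]) -> str:
    lines = ["group_id\tclass\tmember\tspecies\tprototype"]
    for g in groups:
        proto = {m for m, _ in g.prototypes}
        for m in g.member_ids:
            lines.append(
                f"{g.group_id}\t{g.class_label}\t{m}\t{species.get(m, '')}\t"
                f"{int(m in proto)}"
            )
    return "\n".join(lines) + "\n"
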