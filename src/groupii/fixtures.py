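"""Deterministic synthetic reference bundles and mock genomes.

The generator emulates, at desk scale, the sequence universe the pipeline
mines: genomic records containing planted full-length group II introns
(class-specific 5'/3' boundary motifs flanking a Shine-Dalgarno-led IEP
ORF), truncated and frameshifted intron copies, premature-stop copies,
non-group-II RT decoys (retron / DGR / CRISPR-RT families), twintrons, and
clusters of near-identical intron copies across records and species. Every
planted element is written to a truth table so each pipeline stage can be
scored against ground truth.

All output is a pure function of the spec's seed: regenerating with the
same spec yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _jtt
from .boundaries import Side, build_profile
from .homology import local_align
from .orf_analysis import ReferenceIEP
from .references import CuratedIEP, ReferenceBundle
from .screening import DEFINED_CLASSES, RTReference
from .seqio import GenomicRecord, revcomp, write_genbank

#: Classes whose IEP carries the C-terminal endonuclease domain.
EN_CLASSES = {"ML", "CL", "A", "B"}

#: Printed class C boundary consensus strings (DNA alphabet).
CLASS_C_FIVE = "GTNYGCCNRGCATGG"
CLASS_C_THREE = "CCTACYCGAT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "N": "ACGT",
}

_AA = _jtt.AA_ORDER
_SD = "AGGAGG"

# codons per residue, genetic code table 11 (first codon is the canonical one)
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}


@dataclass
class FixtureSpec:
    """Generator settings; the defaults are the package's study conditions."""

    seed: int = 2013
    n_classes: int = 8
    introns_per_class: int = 5
    decoys: dict[str, int] = field(
        default_factory=lambda: {
            "truncated": 6,
            "frameshifted": 5,
            "premature_stop": 5,
            "non_gii_rt": 5,
            "twintron": 4,
        }
    )
    #: (cluster size, target pairwise identity); the first cluster spans two
    #: species, the rest one.
    identity_clusters: list[tuple[int, float]] = field(
        default_factory=lambda: [(3, 0.95), (2, 0.95)]
    )
    record_length: int = 11000
    flank_margin: int = 3100
    iep_length: int = 430
    curated_divergence: float = 0.10
    planted_divergence: float = 0.10
    decoy_family_divergence: float = 0.35
    #: per-column substitution rate applied to planted boundary motifs
    #: (0 by default; the noisy analog condition uses 0.10).
    boundary_mutation_rate: float = 0.0
    ribozyme_5_len: int = 260
    ribozyme_3_len: int = 150
    boundary_training_n: int = 40
    boundary_training_noise: float = 0.05
    reverse_strand_probability: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= len(DEFINED_CLASSES):
            raise ValueError("n_classes must be between 1 and 8")
        if any(v < 0 for v in self.decoys.values()):
            raise ValueError("decoy counts must be >= 0")
        for size, ident in self.identity_clusters:
            if not 0.5 < ident <= 1.0:
                raise ValueError("target identity must be in (0.5, 1.0]")
            if size < 1:
                raise ValueError("cluster size must be >= 1")

    @property
    def classes(self) -> tuple[str, ...]:
        return DEFINED_CLASSES[: self.n_classes]


@dataclass
class TruthRow:
    """Ground truth for one planted element."""

    element_id: str
    accession: str
    kind: str  # intron / truncated / frameshifted / premature_stop / non_gii_rt / twintron
    class_label: str
    strand: str
    intron_interval: Optional[tuple[int, int]]  # [start, end) source forward
    orf_interval: Optional[tuple[int, int]]
    protein: str
    species: str
    expected: str  # "full_length" or the set-aside reason
    group_hint: str = ""  # planted cluster id, "" for singletons


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def to_tsv(self) -> str:
        header = (
            "element_id\taccession\tkind\tclass\tstrand\tintron_start\t"
            "intron_end\torf_start\torf_end\tspecies\texpected\tgroup_hint\tprotein"
        )
        lines = [header]
        for r in self.rows:
            ii = r.intron_interval or ("", "")
            oi = r.orf_interval or ("", "")
            lines.append(
                f"{r.element_id}\t{r.accession}\t{r.kind}\t{r.class_label}\t"
                f"{r.strand}\t{ii[0]}\t{ii[1]}\t{oi[0]}\t{oi[1]}\t{r.species}\t"
                f"{r.expected}\t{r.group_hint}\t{r.protein}"
            )
        return "\n".join(lines) + "\n"

    def to_bed(self) -> str:
        lines = []
        for r in self.rows:
            if r.intron_interval:
                s, e = r.intron_interval
                lines.append(
                    f"{r.accession}\t{s}\t{e}\t{r.element_id}\t0\t{r.strand}"
                )
        return "\n".join(lines) + "\n"


def random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(_AA), size=length - 1, p=_jtt.FREQUENCIES)
    return "M" + "".join(body)


def mutate_protein(
    protein: str, n_subs: int, rng: np.random.Generator
) -> str:
    """Substitute exactly ``n_subs`` positions (never position 0, keeping the
    initiator M) to a uniformly chosen different residue. No indels, so
    identity targets are exact and coordinates are preserved."""
    p = list(protein)
    positions = rng.choice(np.arange(1, len(p)), size=n_subs, replace=False)
    for i in positions:
        alternatives = _AA.replace(p[i], "")
        p[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(p)


def diverge(protein: str, rate: float, rng: np.random.Generator) -> str:
    return mutate_protein(protein, int(round(rate * len(protein))), rng)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def sample_consensus(
    consensus: str, rng: np.random.Generator, noise: float = 0.0
) -> str:
    """One realization of a degenerate consensus: IUPAC positions are drawn
    uniformly from their allowed set; fixed positions are substituted with
    probability ``noise``."""
    out = []
    for c in consensus:
        allowed = IUPAC[c]
        if len(allowed) > 1:
            out.append(allowed[rng.integers(len(allowed))])
        elif noise > 0 and rng.random() < noise:
            out.append("ACGT".replace(c, "")[rng.integers(3)])
        else:
            out.append(c)
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] if aa != "M" or i > 0 else "ATG"
        for i, aa in enumerate(protein)
    )


def _make_consensus_pair(rng: np.random.Generator) -> tuple[str, str]:
    """A generated class consensus with the generic GTGYG.../...AY anchors
    and mild degeneracy comparable to the printed class C strings."""
    five = ["G", "T", "G", "Y", "G"]
    tail = [
        "RY"[rng.integers(2)] if rng.random() < 0.08 else "ACGT"[rng.integers(4)]
        for _ in range(10)
    ]
    five += tail
    three = [
        "RY"[rng.integers(2)] if rng.random() < 0.08 else "ACGT"[rng.integers(4)]
        for _ in range(10)
    ]
    three += ["A", "Y"]
    return "".join(five), "".join(three)


def _proxy_layout(length: int, with_en: bool) -> tuple[dict[str, int], list[str]]:
    domains = ["0", "1", "2", "3", "4", "5", "6", "7", "X"]
    fracs = [0.06, 0.13, 0.20, 0.27, 0.34, 0.42, 0.50, 0.58, 0.72]
    if with_en:
        domains.append("En")
        fracs.append(0.88)
    positions = {d: int(round(f * length)) for d, f in zip(domains, fracs)}
    return positions, domains


def make_reference_bundle(spec: FixtureSpec, validate: bool = True) -> ReferenceBundle:
    """Generate the synthetic reference bundle for a fixture spec.

    Per class: an ancestral IEP, three curated relatives, a reference IEP
    with proxy residues, boundary consensus strings (class C uses the
    printed consensus) with trained and calibrated profiles. The RT
    database holds three group II entries per class plus three decoy RT
    families (retron, DGR, CRISPR-RT) seeded from intron ancestors at
    ~35% divergence. A ninth "unclassified" curated trio exercises the
    unclassified routing.
    """
    if spec.n_classes < 1:
        raise ValueError("need at least one class")
    rng = np.random.default_rng(spec.seed)
    classes = spec.classes
    ancestors: dict[str, str] = {}
    class_refs: dict[str, ReferenceIEP] = {}
    curated: list[CuratedIEP] = []
    consensus: dict[str, tuple[str, str]] = {}
    templates: dict[str, tuple[str, str]] = {}
    training: dict[str, dict[str, list[str]]] = {}
    profiles: dict[str, dict[str, object]] = {}
    queries: list[tuple[str, str]] = []
    rt_db: list[RTReference] = []

    n_curated_subs = int(round(spec.curated_divergence * spec.iep_length))
    for c in classes:
        ancestor = random_protein(rng, spec.iep_length)
        ancestors[c] = ancestor
        queries.append((f"Q_{c}", ancestor))
        proxies, domains = _proxy_layout(spec.iep_length, c in EN_CLASSES)
        if c == "CL":
            for sub in ("CL1", "CL2"):
                class_refs[sub] = ReferenceIEP(
                    class_label=sub,
                    protein=diverge(ancestor, 0.12, rng),
                    proxy_positions=dict(proxies),
                    expected_domains=list(domains),
                )
        else:
            class_refs[c] = ReferenceIEP(
                class_label=c,
                protein=ancestor,
                proxy_positions=dict(proxies),
                expected_domains=list(domains),
            )
        region = (proxies["0"], proxies["X"] + 1)
        for i in range(3):
            label = c if c != "CL" else ("CL1", "CL2", "CL1")[i]
            protein = mutate_protein(ancestor, n_curated_subs, rng)
            curated.append(
                CuratedIEP(
                    id=f"cur_{c}_{i}", class_label=label, protein=protein,
                    region=region, start_codon="ATG",
                )
            )
            rt_db.append(
                RTReference(id=f"rt_gii_{c}_{i}", sequence=protein, category="group_II")
            )
        if c == "C":
            cons = (CLASS_C_FIVE, CLASS_C_THREE)
        else:
            cons = _make_consensus_pair(rng)
        consensus[c] = cons
        # terminal regions of the ribozyme are conserved beyond the printed
        # boundary consensus: the 5' consensus continues into the conserved
        # DI stem and the 3' terminus abuts the highly conserved domains
        # V/VI, so training blocks carry conserved interior context bases
        ctx5 = random_dna(rng, 5)
        ctx3 = random_dna(rng, 10)
        templates[c] = (cons[0] + ctx5, ctx3 + cons[1])
        training[c] = {}
        profiles[c] = {}
        for side, cstr in (
            (Side.FIVE_PRIME, templates[c][0]),
            (Side.THREE_PRIME, templates[c][1]),
        ):
            rows = [
                sample_consensus(cstr, rng, spec.boundary_training_noise)
                for _ in range(spec.boundary_training_n)
            ]
            training[c][side.value] = rows
            profiles[c][side.value] = build_profile(rows, c, side)

    # unclassified curated trio from its own ancestor
    uncl_ancestor = random_protein(rng, spec.iep_length)
    uncl_proxies, _ = _proxy_layout(spec.iep_length, False)
    uncl_region = (uncl_proxies["0"], uncl_proxies["X"] + 1)
    for i in range(3):
        curated.append(
            CuratedIEP(
                id=f"cur_unclassified_{i}",
                class_label="unclassified",
                protein=mutate_protein(uncl_ancestor, n_curated_subs, rng),
                region=uncl_region,
            )
        )

    decoy_families: dict[str, list[str]] = {}
    for fi, category in enumerate(("retron", "DGR", "CRISPR_RT")):
        source = ancestors[classes[fi % len(classes)]]
        family_ancestor = diverge(source, spec.decoy_family_divergence, rng)
        members = [diverge(family_ancestor, 0.10, rng) for _ in range(3)]
        decoy_families[category] = members
        for i, protein in enumerate(members):
            rt_db.append(
                RTReference(id=f"rt_{category}_{i}", sequence=protein, category=category)
            )

    bundle = ReferenceBundle(
        queries=queries,
        rt_db=rt_db,
        curated=curated,
        class_refs=class_refs,
        profiles=profiles,
        consensus=consensus,
        boundary_templates=templates,
        decoy_families=decoy_families,
        training=training,
    )
    if validate:
        _validate_bundle(bundle)
    return bundle


def _validate_bundle(bundle: ReferenceBundle) -> None:
    """Self-consistency: every curated IEP's best match among the other
    curated IEPs must be of its own class."""
    from .homology import DEFAULT_SCHEME
    from .screening import normalize_class

    aligner = DEFAULT_SCHEME.make_aligner()
    for c in bundle.curated:
        best_id, best_score = None, -1.0
        for other in bundle.curated:
            if other.id == c.id:
                continue
            score = aligner.score(c.protein, other.protein)
            if score > best_score:
                best_id, best_score = other, score
        if best_id is None or normalize_class(best_id.class_label) != normalize_class(
            c.class_label
        ):
            raise AssertionError(
                f"bundle inconsistency: {c.id} best-matches "
                f"{best_id.id if best_id else None}"
            )


@dataclass
class _Element:
    """A DNA element to plant plus its internal truth coordinates."""

    element_id: str
    kind: str
    class_label: str
    seq: str
    intron_span: Optional[tuple[int, int]]  # [start, end) within element
    orf_span: Optional[tuple[int, int]]
    protein: str
    expected: str
    species: str
    group_hint: str = ""


def _build_intron(
    protein: str,
    class_label: str,
    bundle: ReferenceBundle,
    spec: FixtureSpec,
    rng: np.random.Generator,
    orf_dna: Optional[str] = None,
    include_three_prime: bool = True,
    parts: Optional[dict] = None,
) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Assemble an intron: 5' motif, ribozyme filler, SD + spacer, ORF,
    filler (domains V/VI stand-in), 3' motif. Returns (sequence,
    intron span, orf span) with spans relative to the element."""
    cons5, cons3 = bundle.boundary_templates[class_label]
    if parts is not None:
        m5, filler_a, spacer, filler_b, m3 = (
            parts["m5"], parts["filler_a"], parts["spacer"],
            parts["filler_b"], parts["m3"],
        )
    else:
        m5 = sample_consensus(cons5, rng, spec.boundary_mutation_rate)
        filler_a = random_dna(rng, spec.ribozyme_5_len)
        spacer = random_dna(rng, 7)
        filler_b = random_dna(rng, spec.ribozyme_3_len)
        m3 = sample_consensus(cons3, rng, spec.boundary_mutation_rate)
    if orf_dna is None:
        orf_dna = reverse_translate(protein, rng) + "TAA"
    pre = m5 + filler_a + _SD + spacer
    if include_three_prime:
        seq = pre + orf_dna + filler_b + m3
    else:
        seq = pre + orf_dna + filler_b
    orf_start = len(pre)
    orf_end = orf_start + len(orf_dna)
    return seq, (0, len(seq)), (orf_start, orf_end)


def _intron_parts(spec: FixtureSpec, rng, cons5: str, cons3: str) -> dict:
    return {
        "m5": sample_consensus(cons5, rng, spec.boundary_mutation_rate),
        "filler_a": random_dna(rng, spec.ribozyme_5_len),
        "spacer": random_dna(rng, 7),
        "filler_b": random_dna(rng, spec.ribozyme_3_len),
        "m3": sample_consensus(cons3, rng, spec.boundary_mutation_rate),
    }


def plant_genome(
    spec: FixtureSpec, bundle: ReferenceBundle
) -> tuple[list[GenomicRecord], TruthTable]:
    """Plant every element of the spec into synthetic GenBank records.

    One element per record (a twintron is one element). Elements land on
    the reverse strand with probability ``reverse_strand_probability``, at
    a position leaving at least ``flank_margin`` nt on each side so the
    3 kb flank contract is exercised without truncation.
    """
    rng = np.random.default_rng(spec.seed + 1)
    classes = spec.classes
    n_subs = int(round(spec.planted_divergence * spec.iep_length))
    elements: list[_Element] = []
    serial = 0

    def next_id(prefix: str) -> str:
        nonlocal serial
        serial += 1
        return f"{prefix}{serial:03d}"

    # full-length singleton introns
    for c in classes:
        for i in range(spec.introns_per_class):
            protein = mutate_protein(dict(bundle.queries)[f"Q_{c}"], n_subs, rng)
            seq, ispan, ospan = _build_intron(protein, c, bundle, spec, rng)
            elements.append(
                _Element(
                    element_id=next_id("intron_"),
                    kind="intron",
                    class_label=c,
                    seq=seq,
                    intron_span=ispan,
                    orf_span=ospan,
                    protein=protein,
                    expected="full_length",
                    species="",
                )
            )

    # identity clusters: near-identical intron copies across records.
    # Member substitutions are pairwise disjoint and split proportionally
    # between the domain 0->X region and the rest, so both the planted
    # whole-protein identity and the region distance used for grouping are
    # deterministic (the 0.061 <-> 95% margin is thin).
    ancestors = dict(bundle.queries)
    for j, (size, ident) in enumerate(spec.identity_clusters):
        c = classes[j % len(classes)]
        base = mutate_protein(ancestors[f"Q_{c}"], n_subs, rng)
        parts = _intron_parts(spec, rng, *bundle.boundary_templates[c])
        base_codons = [
            _CODONS[aa][rng.integers(len(_CODONS[aa]))] if k else "ATG"
            for k, aa in enumerate(base)
        ]
        k_subs = int(round((1.0 - ident) / 2.0 * len(base)))
        proxies, _ = _proxy_layout(spec.iep_length, c in EN_CLASSES)
        r_start, r_end = proxies["0"], proxies["X"] + 1
        k_in = int(round(k_subs * (r_end - r_start) / len(base)))
        inside_pool = list(range(max(1, r_start), r_end))
        outside_pool = [
            p for p in range(1, len(base)) if not r_start <= p < r_end
        ]
        cluster_id = f"cluster{j}"
        for m in range(size):
            chosen = []
            for pool, count in ((inside_pool, k_in), (outside_pool, k_subs - k_in)):
                picks = rng.choice(len(pool), size=count, replace=False)
                chosen.extend(pool[i] for i in picks)
                for i in sorted(picks, reverse=True):
                    pool.pop(i)
            protein = list(base)
            for i in chosen:
                protein[i] = _AA.replace(protein[i], "")[rng.integers(19)]
            protein = "".join(protein)
            codons = [
                base_codons[k]
                if protein[k] == base[k]
                else _CODONS[protein[k]][rng.integers(len(_CODONS[protein[k]]))]
                for k in range(len(protein))
            ]
            orf_dna = "".join(codons) + "TAA"
            seq, ispan, ospan = _build_intron(
                protein, c, bundle, spec, rng, orf_dna=orf_dna, parts=parts
            )
            species = (
                f"Synthetica {cluster_id}B"
                if (j == 0 and m == size - 1 and size >= 2)
                else f"Synthetica {cluster_id}A"
            )
            elements.append(
                _Element(
                    element_id=next_id("cluster_intron_"),
                    kind="intron",
                    class_label=c,
                    seq=seq,
                    intron_span=ispan,
                    orf_span=ospan,
                    protein=protein,
                    expected="full_length",
                    species=species,
                    group_hint=cluster_id,
                )
            )

    # decoys
    counts = spec.decoys
    refs = {c: dict(bundle.queries)[f"Q_{c}"] for c in classes}
    for i in range(counts.get("truncated", 0)):
        c = classes[i % len(classes)]
        full = mutate_protein(refs[c], n_subs, rng)
        ref_label = c if c != "CL" else "CL1"
        cut = bundle.class_refs[ref_label].proxy_positions["4"] + 10
        trunc = full[:cut]
        orf_dna = reverse_translate(trunc, rng) + random_dna(rng, 90)
        seq, ispan, ospan = _build_intron(
            trunc, c, bundle, spec, rng, orf_dna=orf_dna, include_three_prime=False
        )
        elements.append(
            _Element(next_id("trunc_"), "truncated", c, seq, None,
                     ospan, trunc, "missing", "")
        )
    for i in range(counts.get("frameshifted", 0)):
        c = classes[(i + 2) % len(classes)]
        protein = mutate_protein(refs[c], n_subs, rng)
        codons = reverse_translate(protein, rng)
        # break between the proxies of domains 4 and 5 so the two resulting
        # HSPs cover disjoint proxy sets and the decoy exits at the ORF stage
        half = 3 * int(0.38 * len(protein))
        orf_dna = codons[:half] + "A" + codons[half:] + "TAA"
        seq, ispan, ospan = _build_intron(
            protein, c, bundle, spec, rng, orf_dna=orf_dna
        )
        elements.append(
            _Element(next_id("fshift_"), "frameshifted", c, seq, ispan,
                     ospan, protein, "multiple_hsps", "")
        )
    for i in range(counts.get("premature_stop", 0)):
        c = classes[(i + 4) % len(classes)]
        protein = mutate_protein(refs[c], n_subs, rng)
        codons = [
            _CODONS[aa][rng.integers(len(_CODONS[aa]))] if k else "ATG"
            for k, aa in enumerate(protein)
        ]
        codons[int(0.6 * len(codons))] = "TAA"
        orf_dna = "".join(codons) + "TAA"
        seq, ispan, ospan = _build_intron(
            protein, c, bundle, spec, rng, orf_dna=orf_dna
        )
        elements.append(
            _Element(next_id("pstop_"), "premature_stop", c, seq, ispan,
                     ospan, protein, "premature_stop", "")
        )
    families = sorted(bundle.decoy_families)
    for i in range(counts.get("non_gii_rt", 0)):
        category = families[i % len(families)]
        member = bundle.decoy_families[category][i % 3]
        protein = diverge(member, 0.05, rng)
        orf_dna = reverse_translate(protein, rng) + "TAA"
        seq = _SD + random_dna(rng, 7) + orf_dna
        ospan = (len(_SD) + 7, len(_SD) + 7 + len(orf_dna))
        elements.append(
            _Element(next_id("rtdecoy_"), "non_gii_rt", category, seq, None,
                     ospan, protein, "non_group_II", "")
        )
    for i in range(counts.get("twintron", 0)):
        c = classes[(i + 6) % len(classes)]
        outer = mutate_protein(refs[c], n_subs, rng)
        inner = mutate_protein(refs[c], n_subs, rng)
        inner_seq, _, _ = _build_intron(inner, c, bundle, spec, rng)
        cons5, cons3 = bundle.boundary_templates[c]
        m5 = sample_consensus(cons5, rng, spec.boundary_mutation_rate)
        m3 = sample_consensus(cons3, rng, spec.boundary_mutation_rate)
        filler_a = random_dna(rng, spec.ribozyme_5_len)
        spacer = random_dna(rng, 7)
        orf1 = reverse_translate(outer, rng) + "TAA"
        mid = random_dna(rng, 300)
        tail = random_dna(rng, 200)
        seq = m5 + filler_a + _SD + spacer + orf1 + mid + inner_seq + tail + m3
        o1 = len(m5) + len(filler_a) + len(_SD) + len(spacer)
        elements.append(
            _Element(next_id("twin_"), "twintron", c, seq, (0, len(seq)),
                     (o1, o1 + len(orf1)), outer, "extra", "")
        )

    records: list[GenomicRecord] = []
    rows: list[TruthRow] = []
    for idx, el in enumerate(elements):
        L = spec.record_length
        if len(el.seq) + 2 * spec.flank_margin > L:
            raise ValueError(
                f"record length {L} too short for element {el.element_id}"
            )
        background = random_dna(rng, L)
        p = int(rng.integers(spec.flank_margin, L - spec.flank_margin - len(el.seq)))
        forward = background[:p] + el.seq + background[p + len(el.seq) :]
        minus = rng.random() < spec.reverse_strand_probability
        accession = f"SYN{idx:04d}"
        species = el.species or f"Synthetica isolate{idx}"

        def fwd_interval(span):
            if span is None:
                return None
            s, e = p + span[0], p + span[1]
            if minus:
                return (L - e, L - s)
            return (s, e)

        seq_final = revcomp(forward) if minus else forward
        records.append(
            GenomicRecord(
                accession=accession,
                version=f"{accession}.1",
                sequence=seq_final,
                taxonomy_lineage=["Bacteria", "Synthetica"],
                organism=species,
                raw_entry="",
            )
        )
        rows.append(
            TruthRow(
                element_id=el.element_id,
                accession=accession,
                kind=el.kind,
                class_label=el.class_label,
                strand="-" if minus else "+",
                intron_interval=fwd_interval(el.intron_span),
                orf_interval=fwd_interval(el.orf_span),
                protein=el.protein,
                species=species,
                expected=el.expected,
                group_hint=el.group_hint,
            )
        )
    for rec in records:
        rec.raw_entry = write_genbank([rec])
    return records, TruthTable(rows)


def fixture_corpus_text(records: Sequence[GenomicRecord]) -> str:
    return "".join(r.raw_entry for r in records)
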