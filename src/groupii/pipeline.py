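"""Pipeline orchestration over the eight storage stages.

Candidates accumulate verdicts while moving through storage stages 0-7;
at each stage the retained set shrinks and set-aside candidates are parked
with a reason, so every initial candidate is accounted for at every later
stage. All intermediates are serialized as plain text (JSON state plus
TSV/FASTA reports) under ``storage/<n>/``.

Stage map (the classic program names in parentheses):

0. search + download + storage (blast_and_parse, DNA_sequence_download,
   create_storage): translated search of the queries, pooling into unique
   loci, taxonomy bucketing, window extraction with 3 kb flanks.
1. RT filtering (filter_out_non_gpII_rts)
2. class assignment (find_intron_class)
3. domain inventory (find_orf_domains)
4. ORF intactness + IEP assignment (find_orf)
5. boundary scanning (find_intron_boundaries)
6. boundary resolution + intron sequence (generate_rna_sequences)
7. redundancy grouping + prototypes (group_candidates, select_prototypes)

The final output goes to two folders: ``final/full_length`` (all
full-length putatively functional introns) and ``final/prototypes`` (the
non-redundant set, keeping one prototype per species within a group).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .boundaries import (
    BoundaryBin,
    BoundaryCall,
    BoundaryCandidate,
    IntronCall,
    IntronStatus,
    Side,
    generate_intron,
    resolve_boundaries,
    scan_boundaries,
)
from .homology import DEFAULT_SCHEME, translated_search, pool_hits
from .orf_analysis import (
    DomainCategory,
    DomainInventory,
    IEPSequence,
    OrfStatus,
    OrfIssue,
    assign_iep,
    candidate_region,
    domain_inventory,
    orf_intactness,
    pick_reference,
)
from .redundancy import (
    align_orf_region,
    distance_matrix,
    group_by_threshold,
    groups_to_tsv,
    select_prototypes,
)
from .references import ReferenceBundle
from .screening import RTVerdictValue, assign_class, rt_verdict
from .seqio import (
    GenomicRecord,
    SequenceWindow,
    TaxonBucket,
    classify_taxon,
    extract_window,
    write_fasta,
)

logger = logging.getLogger("groupii")

N_STAGES = 8


def _json_scalar(obj):
    """JSON fallback for numpy scalar types leaking out of array code."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


@dataclass
class PipelineConfig:
    evalue_cutoff: float = 1e-20
    flank_nt: int = 3000
    rt_vote_threshold: int = 3
    include_possible_rts: bool = False
    tier_minimum: str = "high"
    admit_medium_low: bool = False
    length_bounds: tuple[int, int] = (400, 8000)
    distance_threshold: float = 0.061
    taxon_bucket: str = TaxonBucket.BACTERIA_ARCHAEA.value
    gap_allowance_codons: int = 2
    coverage_fraction: float = 0.95
    prescreen: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0 or self.flank_nt <= 0:
            raise ValueError("thresholds must be positive")
        self.length_bounds = tuple(self.length_bounds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["length_bounds"] = list(self.length_bounds)
        return yaml.safe_dump(d, sort_keys=True)


@dataclass
class CandidateIntron:
    """Per-candidate state accumulating verdicts through stages 0-7."""

    candidate_id: str
    window: SequenceWindow
    species: str
    taxon_bucket: str
    stage_reached: int = 0
    set_aside_reason: Optional[str] = None
    set_aside_stage: Optional[int] = None
    rt_verdict: Optional[dict] = None
    class_assignment: Optional[dict] = None
    domain_inventory: Optional[dict] = None
    orf_status: Optional[dict] = None
    iep: Optional[dict] = None
    orf_span_window: Optional[tuple[int, int]] = None
    orf_region_aa: Optional[tuple[int, int]] = None
    boundary_call: Optional[dict] = None
    intron_call: Optional[dict] = None
    group_id: Optional[str] = None
    is_prototype: bool = False

    @property
    def active(self) -> bool:
        return self.set_aside_reason is None

    def set_aside(self, reason: str, stage: int) -> None:
        self.set_aside_reason = reason
        self.set_aside_stage = stage

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = dataclasses.asdict(self.window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateIntron":
        d = dict(d)
        w = dict(d.pop("window"))
        w["source_interval"] = tuple(w["source_interval"])
        if w.get("hit_interval_window"):
            w["hit_interval_window"] = tuple(w["hit_interval_window"])
        out = cls(window=SequenceWindow(**w), **d)
        if out.orf_span_window:
            out.orf_span_window = tuple(out.orf_span_window)
        if out.orf_region_aa:
            out.orf_region_aa = tuple(out.orf_region_aa)
        return out


@dataclass
class PipelineState:
    stage: int
    candidates: list[CandidateIntron]
    groups_tsv: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "candidates": [c.to_dict() for c in self.candidates],
                "groups_tsv": self.groups_tsv,
            },
            sort_keys=True,
            default=_json_scalar,
        )

    @classmethod
    def from_json(cls, text: str) -> "PipelineState":
        d = json.loads(text)
        return cls(
            stage=d["stage"],
            candidates=[CandidateIntron.from_dict(c) for c in d["candidates"]],
            groups_tsv=d.get("groups_tsv", ""),
        )


# ---------------------------------------------------------------- stages


def _stage0(
    records: Sequence[GenomicRecord],
    bundle: ReferenceBundle,
    config: PipelineConfig,
) -> PipelineState:
    all_hsps = []
    by_accession = {}
    for rec in records:
        by_accession[rec.accession] = rec
        for qid, qseq in bundle.queries:
            all_hsps.extend(
                translated_search(
                    qseq,
                    rec.sequence,
                    DEFAULT_SCHEME,
                    evalue_cutoff=config.evalue_cutoff,
                    query_id=qid,
                    subject_accession=rec.accession,
                    prescreen=config.prescreen,
                )
            )
    loci = pool_hits(all_hsps)
    candidates = []
    for i, locus in enumerate(loci):
        rec = by_accession[locus.accession]
        bucket = classify_taxon(rec)
        window = extract_window(
            rec,
            locus.interval,
            locus.strand,
            flank_nt=config.flank_nt,
            candidate_id=f"cand{i:04d}_{locus.accession}",
        )
        cand = CandidateIntron(
            candidate_id=window.candidate_id,
            window=window,
            species=rec.organism,
            taxon_bucket=bucket.value,
            stage_reached=0,
        )
        if bucket.value != config.taxon_bucket:
            cand.set_aside(f"taxonomy_{bucket.value}", 0)
        candidates.append(cand)
    return PipelineState(stage=0, candidates=candidates)


def _stage1(state: PipelineState, bundle: ReferenceBundle, config: PipelineConfig):
    for cand in state.candidates:
        if not cand.active:
            continue
        verdict = rt_verdict(
            cand.window,
            bundle.rt_db,
            DEFAULT_SCHEME,
            evalue_cutoff=config.evalue_cutoff,
            probable_votes=config.rt_vote_threshold,
            prescreen=config.prescreen,
        )
        cand.rt_verdict = {
            "value": verdict.value.value,
            "top_matches": [list(t) for t in verdict.top_matches],
        }
        if verdict.value is RTVerdictValue.NON_GROUP_II:
            cand.set_aside("non_group_II", 1)
        elif verdict.value is RTVerdictValue.POSSIBLE and not config.include_possible_rts:
            cand.set_aside("possible_rt", 1)
        else:
            cand.stage_reached = 1
    state.stage = 1
    return state


def _stage2(state: PipelineState, bundle: ReferenceBundle, config: PipelineConfig):
    for cand in state.candidates:
        if not cand.active:
            continue
        assignment = assign_class(
            cand.window,
            bundle.curated,
            DEFAULT_SCHEME,
            evalue_cutoff=config.evalue_cutoff,
            prescreen=config.prescreen,
        )
        cand.class_assignment = {
            "intron_class": assignment.intron_class,
            "closest_relative_id": assignment.closest_relative_id,
            "top_matches": [list(t) for t in assignment.top_matches],
        }
        if assignment.closest_relative_id is None:
            cand.set_aside("no_class_hits", 2)
        else:
            cand.stage_reached = 2
    state.stage = 2
    return state


def _stage3(state: PipelineState, bundle: ReferenceBundle, config: PipelineConfig):
    references = list(bundle.class_refs.values())
    for cand in state.candidates:
        if not cand.active:
            continue
        ref = pick_reference(
            references,
            cand.class_assignment["intron_class"],
            cand.window,
            prescreen=config.prescreen,
        )
        inventory = domain_inventory(
            cand.window,
            ref,
            DEFAULT_SCHEME,
            evalue_cutoff=config.evalue_cutoff,
            prescreen=config.prescreen,
        )
        cand.domain_inventory = {
            "counts": inventory.counts,
            "category": inventory.category.value,
            "hsp_count": inventory.hsp_count,
            "reference": ref.class_label,
        }
        if inventory.category is not DomainCategory.NORMAL:
            cand.set_aside(inventory.category.value, 3)
        else:
            cand.stage_reached = 3
    state.stage = 3
    return state


def _stage4(state: PipelineState, bundle: ReferenceBundle, config: PipelineConfig):
    for cand in state.candidates:
        if not cand.active:
            continue
        relative = bundle.curated_by_id(
            cand.class_assignment["closest_relative_id"]
        )
        status = orf_intactness(
            cand.window,
            relative.protein,
            relative.region,
            DEFAULT_SCHEME,
            evalue_cutoff=config.evalue_cutoff,
            gap_allowance_codons=config.gap_allowance_codons,
            coverage_fraction=config.coverage_fraction,
            prescreen=config.prescreen,
        )
        cand.orf_status = {
            "intact": status.intact,
            "issues": [i.value for i in status.issues],
            "hsp_count": status.hsp_count,
        }
        if not status.intact:
            cand.set_aside(status.issues[0].value, 4)
            continue
        iep = assign_iep(
            cand.window,
            relative.protein,
            relative.start_codon,
            DEFAULT_SCHEME,
            prescreen=config.prescreen,
        )
        if iep is None:
            cand.set_aside("no_start_codon", 4)
            continue
        cand.iep = dataclasses.asdict(iep)
        start = iep.start_pos_window
        cand.orf_span_window = (start, start + 3 * len(iep.protein) + 3)
        ref = pick_reference(
            list(bundle.class_refs.values()),
            cand.class_assignment["intron_class"],
            cand.window,
            prescreen=config.prescreen,
        )
        cand.orf_region_aa = candidate_region(iep.protein, ref)
        cand.stage_reached = 4
    state.stage = 4
    return state


def _stage5(state: PipelineState, bundle: ReferenceBundle, config: PipelineConfig):
    for cand in state.candidates:
        if not cand.active:
            continue
        p5, p3 = bundle.profiles_for(cand.class_assignment["intron_class"])
        call = scan_boundaries(cand.window, p5, p3)
        cand.boundary_call = {
            "bin": call.bin.value,
            "tier": call.tier,
            "candidates_5": [dataclasses.asdict(c) for c in call.candidates_5],
            "candidates_3": [dataclasses.asdict(c) for c in call.candidates_3],
        }
        cand.stage_reached = 5
    state.stage = 5
    return state


def _rebuild_call(d: dict) -> BoundaryCall:
    def mk(cd):
        cd = dict(cd)
        cd["side"] = Side(cd["side"])
        return BoundaryCandidate(**cd)

    return BoundaryCall(
        bin=BoundaryBin(d["bin"]),
        tier=d["tier"],
        candidates_5=[mk(c) for c in d["candidates_5"]],
        candidates_3=[mk(c) for c in d["candidates_3"]],
    )


def _stage6(state: PipelineState, bundle: ReferenceBundle, config: PipelineConfig):
    for cand in state.candidates:
        if not cand.active:
            continue
        call = _rebuild_call(cand.boundary_call)
        intron = resolve_boundaries(
            call,
            cand.orf_span_window,
            length_bounds=config.length_bounds,
            tier_minimum=config.tier_minimum,
            admit_single_submaximal=config.admit_medium_low,
        )
        if intron.status is IntronStatus.HAVE_BOUNDARIES:
            generate_intron(cand.window, intron)
            cand.stage_reached = 6
        else:
            cand.set_aside("ambiguous_boundaries", 6)
        cand.intron_call = dataclasses.asdict(intron)
        cand.intron_call["status"] = intron.status.value
    state.stage = 6
    return state


def _stage7(state: PipelineState, bundle: ReferenceBundle, config: PipelineConfig):
    active = [c for c in state.candidates if c.active]
    by_class: dict[str, list[CandidateIntron]] = {}
    for cand in active:
        by_class.setdefault(cand.class_assignment["intron_class"], []).append(cand)
    species = {c.candidate_id: c.species for c in active}
    lengths = {
        c.candidate_id: c.intron_call["end_3"] - c.intron_call["start_5"] + 1
        for c in active
    }
    all_groups = []
    for class_label in sorted(by_class):
        members = by_class[class_label]
        regions = []
        for c in members:
            protein = c.iep["protein"]
            a, b = c.orf_region_aa
            regions.append((c.candidate_id, protein[a:b]))
        aligned = align_orf_region(regions)
        dm = distance_matrix(aligned)
        groups = group_by_threshold(
            dm, threshold=config.distance_threshold, class_label=class_label
        )
        for g in groups:
            select_prototypes(g, species, lengths)
            by_id = {c.candidate_id: c for c in members}
            proto = {m for m, _ in g.prototypes}
            for m in g.member_ids:
                by_id[m].group_id = g.group_id
                by_id[m].is_prototype = m in proto
                by_id[m].stage_reached = 7
            g.dna_alignment = [
                (m, by_id[m].intron_call["intron_seq"]) for m in g.member_ids
            ]
        all_groups.extend(groups)
    state.groups_tsv = groups_to_tsv(all_groups, species)
    state.stage = 7
    return state


_STAGE_FUNCS = {
    1: _stage1, 2: _stage2, 3: _stage3, 4: _stage4,
    5: _stage5, 6: _stage6, 7: _stage7,
}


# ------------------------------------------------------------- persistence


def _stage_dir(workdir: Path, n: int) -> Path:
    return Path(workdir) / "storage" / str(n)


def _write_stage(state: PipelineState, workdir: Path) -> None:
    d = _stage_dir(workdir, state.stage)
    d.mkdir(parents=True, exist_ok=True)
    (d / "state.json").write_text(state.to_json())
    retained = [c for c in state.candidates if c.active]
    lines = ["candidate_id\taccession\tstrand\tstage_reached\tclass\tstatus\treason"]
    for c in state.candidates:
        cls = c.class_assignment["intron_class"] if c.class_assignment else ""
        status = "retained" if c.active else "set_aside"
        lines.append(
            f"{c.candidate_id}\t{c.window.source_accession}\t"
            f"{c.window.source_strand}\t{c.stage_reached}\t{cls}\t{status}\t"
            f"{c.set_aside_reason or ''}"
        )
    (d / "candidates.tsv").write_text("\n".join(lines) + "\n")
    (d / "windows.fasta").write_text(
        write_fasta([(c.candidate_id, c.window.window_seq) for c in retained])
    )
    aside = [c for c in state.candidates if not c.active]
    if aside:
        sd = d / "set_aside"
        sd.mkdir(exist_ok=True)
        by_reason: dict[str, list[CandidateIntron]] = {}
        for c in aside:
            by_reason.setdefault(c.set_aside_reason, []).append(c)
        for reason, cands in sorted(by_reason.items()):
            (sd / f"{reason}.tsv").write_text(
                "".join(f"{c.candidate_id}\t{c.set_aside_stage}\n" for c in cands)
            )
    if state.groups_tsv:
        (d / "groups.tsv").write_text(state.groups_tsv)


def _load_stage(workdir: Path, n: int) -> PipelineState:
    path = _stage_dir(workdir, n) / "state.json"
    if not path.is_file():
        raise FileNotFoundError(
            f"storage stage {n} is missing ({path}); run stage {n} first"
        )
    return PipelineState.from_json(path.read_text())


def run_stage(
    n: int,
    workdir: str | Path,
    bundle: ReferenceBundle,
    config: PipelineConfig,
    records: Optional[Sequence[GenomicRecord]] = None,
) -> PipelineState:
    """Run stage ``n`` from the serialized output of stage ``n - 1``.

    Stage 0 requires ``records``; later stages load their input from
    ``storage/<n-1>/state.json`` and fail with a clear message if it is
    missing.
    """
    workdir = Path(workdir)
    if n == 0:
        if records is None:
            raise ValueError("stage 0 needs input records")
        state = _stage0(records, bundle, config)
    else:
        if n not in _STAGE_FUNCS:
            raise ValueError(f"no such stage: {n}")
        state = _load_stage(workdir, n - 1)
        state = _STAGE_FUNCS[n](state, bundle, config)
    _write_stage(state, workdir)
    logger.info(
        "stage %d: %d retained / %d total",
        n,
        sum(c.active for c in state.candidates),
        len(state.candidates),
    )
    return state


# ---------------------------------------------------------- final outputs


def _gff3_line(c: CandidateIntron) -> str:
    w = c.window
    s, e = w.interval_to_source(
        c.intron_call["start_5"], c.intron_call["end_3"] + 1
    )
    return (
        f"{w.source_accession}\tgroupii\tgroup_II_intron\t{s + 1}\t{e}\t.\t"
        f"{w.source_strand}\t.\tID={c.candidate_id};class="
        f"{c.class_assignment['intron_class']};tier={c.intron_call['tier']}"
    )


def _write_final(state: PipelineState, workdir: Path) -> None:
    active = [c for c in state.candidates if c.active]
    for folder, members in (
        ("full_length", active),
        ("prototypes", [c for c in active if c.is_prototype]),
    ):
        d = Path(workdir) / "final" / folder
        d.mkdir(parents=True, exist_ok=True)
        (d / "introns.fasta").write_text(
            write_fasta([(c.candidate_id, c.intron_call["intron_seq"]) for c in members])
        )
        (d / "ieps.fasta").write_text(
            write_fasta([(c.candidate_id, c.iep["protein"]) for c in members])
        )
        lines = [
            "candidate_id\taccession\tspecies\tclass\tgroup_id\tprototype\t"
            "intron_start_window\tintron_end_window\tlength\ttier"
        ]
        for c in members:
            s5, e3 = c.intron_call["start_5"], c.intron_call["end_3"]
            lines.append(
                f"{c.candidate_id}\t{c.window.source_accession}\t{c.species}\t"
                f"{c.class_assignment['intron_class']}\t{c.group_id}\t"
                f"{int(c.is_prototype)}\t{s5}\t{e3}\t{e3 - s5 + 1}\t"
                f"{c.intron_call['tier']}"
            )
        (d / "table.tsv").write_text("\n".join(lines) + "\n")
        gff = ["##gff-version 3"] + [_gff3_line(c) for c in members]
        (d / "introns.gff3").write_text("\n".join(gff) + "\n")
        bed = []
        for c in members:
            s, e = c.window.interval_to_source(
                c.intron_call["start_5"], c.intron_call["end_3"] + 1
            )
            bed.append(
                f"{c.window.source_accession}\t{s}\t{e}\t{c.candidate_id}\t0\t"
                f"{c.window.source_strand}"
            )
        (d / "introns.bed").write_text("\n".join(bed) + "\n")


def run_all(
    records: Sequence[GenomicRecord],
    bundle: ReferenceBundle,
    config: Optional[PipelineConfig] = None,
    workdir: Optional[str | Path] = None,
) -> PipelineState:
    """Run all stages end to end; when ``workdir`` is given, storage trees
    and the two final output folders are written there."""
    config = config or PipelineConfig()
    if not records:
        logger.warning("empty corpus: producing empty outputs")
    state = _stage0(records, bundle, config)
    if workdir is not None:
        _write_stage(state, Path(workdir))
    for n in range(1, N_STAGES):
        state = _STAGE_FUNCS[n](state, bundle, config)
        if workdir is not None:
            _write_stage(state, Path(workdir))
    if workdir is not None:
        _write_final(state, Path(workdir))
    return state


def report(state: PipelineState) -> dict:
    """Per-stage retention counts and set-aside reasons, plus a
    per-candidate audit trail."""
    total = len(state.candidates)
    stages = []
    for n in range(state.stage + 1):
        retained = sum(
            1
            for c in state.candidates
            if c.active or (c.set_aside_stage is not None and c.set_aside_stage > n)
        )
        stages.append({"stage": n, "retained": retained, "total": total})
    reasons: dict[str, int] = {}
    for c in state.candidates:
        if not c.active:
            reasons[c.set_aside_reason] = reasons.get(c.set_aside_reason, 0) + 1
    audit = {
        c.candidate_id: {
            "stage_reached": c.stage_reached,
            "set_aside_stage": c.set_aside_stage,
            "reason": c.set_aside_reason,
            "class": c.class_assignment["intron_class"] if c.class_assignment else None,
            "group_id": c.group_id,
            "prototype": c.is_prototype,
        }
        for c in state.candidates
    }
    return {"stages": stages, "set_aside_reasons": reasons, "candidates": audit}


def report_tsv(state: PipelineState) -> str:
    rep = report(state)
    lines = ["stage\tretained\ttotal"]
    for s in rep["stages"]:
        lines.append(f"{s['stage']}\t{s['retained']}\t{s['total']}")
    lines.append("")
    lines.append("reason\tcount")
    for reason, count in sorted(rep["set_aside_reasons"].items()):
        lines.append(f"{reason}\t{count}")
    return "\n".join(lines) + "\n"
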