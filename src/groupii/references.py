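"""Reference bundle: query ORFs, curated introns, RT types, per-class
reference IEPs, and boundary profiles.

The pipeline's knowledge of group II introns lives in a
:class:`ReferenceBundle`: the query proteins used for the initial
translated search, a curated intron set with class labels and domain
spans, a categorized bacterial RT database, one reference IEP per
class/subclass with per-domain proxy residues, and per-class 5'/3'
boundary profiles. Bundles are stored as plain text (FASTA + TSV sidecars +
JSON) so users can swap in their own reference sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .boundaries import BoundaryProfile, Side
from .orf_analysis import ReferenceIEP
from .screening import RTReference
from .seqio import read_fasta, write_fasta


@dataclass
class CuratedIEP:
    """One entry of the curated intron set."""

    id: str
    class_label: str  # ML, CL1, CL2, A..F, or "unclassified"
    protein: str
    #: [start, end) aa span of RT domain 0 through domain X.
    region: tuple[int, int]
    start_codon: str = "ATG"
    dna: Optional[str] = None


@dataclass
class ReferenceBundle:
    queries: list[tuple[str, str]]
    rt_db: list[RTReference]
    curated: list[CuratedIEP]
    class_refs: dict[str, ReferenceIEP]
    #: class label -> {"five_prime": profile, "three_prime": profile}
    profiles: dict[str, dict[str, BoundaryProfile]]
    #: class label -> (5' consensus, 3' consensus) in the DNA alphabet.
    consensus: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: class label -> full training templates (consensus plus conserved
    #: interior context bases) used to plant and train boundary blocks.
    boundary_templates: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: RT category -> member proteins (used by the fixture generator).
    decoy_families: dict[str, list[str]] = field(default_factory=dict)
    #: class label -> side -> training alignment rows.
    training: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def curated_by_id(self, cid: str) -> CuratedIEP:
        for c in self.curated:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def profiles_for(self, intron_class: str) -> tuple[list, list]:
        """(5' profiles, 3' profiles) for a class; unclassified/undefined
        candidates are scanned with the profiles of all classes."""
        if intron_class in self.profiles:
            p = self.profiles[intron_class]
            return [p["five_prime"]], [p["three_prime"]]
        fives = [p["five_prime"] for _, p in sorted(self.profiles.items())]
        threes = [p["three_prime"] for _, p in sorted(self.profiles.items())]
        return fives, threes


def read_training_alignment(path: str | Path) -> list[str]:
    """Boundary training block from an aligned FASTA or Stockholm file."""
    from Bio import AlignIO

    path = Path(path)
    fmt = (
        "stockholm"
        if path.read_text().lstrip().startswith("# STOCKHOLM")
        else "fasta"
    )
    alignment = AlignIO.read(str(path), fmt)
    return [str(rec.seq).upper() for rec in alignment]


def save_bundle(bundle: ReferenceBundle, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "queries.fasta").write_text(write_fasta(bundle.queries))
    (d / "rt_db.fasta").write_text(
        write_fasta([(r.id, r.sequence) for r in bundle.rt_db])
    )
    (d / "rt_db.tsv").write_text(
        "id\tcategory\n" + "".join(f"{r.id}\t{r.category}\n" for r in bundle.rt_db)
    )
    (d / "curated.fasta").write_text(
        write_fasta([(c.id, c.protein) for c in bundle.curated])
    )
    (d / "curated.tsv").write_text(
        "id\tclass\tregion_start\tregion_end\tstart_codon\n"
        + "".join(
            f"{c.id}\t{c.class_label}\t{c.region[0]}\t{c.region[1]}\t{c.start_codon}\n"
            for c in bundle.curated
        )
    )
    refs = {
        label: {
            "class_label": r.class_label,
            "protein": r.protein,
            "proxy_positions": r.proxy_positions,
            "expected_domains": r.expected_domains,
            "annotated_start_codon": r.annotated_start_codon,
        }
        for label, r in bundle.class_refs.items()
    }
    (d / "class_refs.json").write_text(json.dumps(refs, indent=1, sort_keys=True))
    profs = {
        label: {side: p.to_dict() for side, p in sides.items()}
        for label, sides in bundle.profiles.items()
    }
    meta = {
        "profiles": profs,
        "consensus": {k: list(v) for k, v in bundle.consensus.items()},
        "boundary_templates": {
            k: list(v) for k, v in bundle.boundary_templates.items()
        },
        "decoy_families": bundle.decoy_families,
    }
    (d / "profiles.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    tdir = d / "training"
    tdir.mkdir(exist_ok=True)
    for label, sides in bundle.training.items():
        for side, rows in sides.items():
            (tdir / f"{label}_{side}.fasta").write_text(
                write_fasta([(f"{label}_{side}_{i}", s) for i, s in enumerate(rows)])
            )


def load_bundle(directory: str | Path) -> ReferenceBundle:
    d = Path(directory)
    queries = read_fasta((d / "queries.fasta").read_text())
    rt_seqs = dict(read_fasta((d / "rt_db.fasta").read_text()))
    rt_db = []
    for line in (d / "rt_db.tsv").read_text().splitlines()[1:]:
        rid, cat = line.split("\t")
        rt_db.append(RTReference(id=rid, sequence=rt_seqs[rid], category=cat))
    cur_seqs = dict(read_fasta((d / "curated.fasta").read_text()))
    curated = []
    for line in (d / "curated.tsv").read_text().splitlines()[1:]:
        cid, cls, rs, re_, sc = line.split("\t")
        curated.append(
            CuratedIEP(
                id=cid, class_label=cls, protein=cur_seqs[cid],
                region=(int(rs), int(re_)), start_codon=sc,
            )
        )
    refs_raw = json.loads((d / "class_refs.json").read_text())
    class_refs = {
        label: ReferenceIEP(
            class_label=r["class_label"],
            protein=r["protein"],
            proxy_positions=r["proxy_positions"],
            expected_domains=r["expected_domains"],
            annotated_start_codon=r["annotated_start_codon"],
        )
        for label, r in refs_raw.items()
    }
    meta = json.loads((d / "profiles.json").read_text())
    profiles = {
        label: {side: BoundaryProfile.from_dict(p) for side, p in sides.items()}
        for label, sides in meta["profiles"].items()
    }
    training: dict[str, dict[str, list[str]]] = {}
    tdir = d / "training"
    if tdir.is_dir():
        for f in sorted(tdir.glob("*.fasta")):
            label, side = f.stem.rsplit("_", 2)[0], "_".join(f.stem.rsplit("_", 2)[1:])
            training.setdefault(label, {})[side] = [
                s for _, s in read_fasta(f.read_text())
            ]
    return ReferenceBundle(
        queries=queries,
        rt_db=rt_db,
        curated=curated,
        class_refs=class_refs,
        profiles=profiles,
        consensus={k: tuple(v) for k, v in meta.get("consensus", {}).items()},
        boundary_templates={
            k: tuple(v) for k, v in meta.get("boundary_templates", {}).items()
        },
        decoy_families=meta.get("decoy_families", {}),
        training=training,
    )
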