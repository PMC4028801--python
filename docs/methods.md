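# Methods

This note describes the models and procedures behind `groupii`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Translated homology search

The search engine emulates a translated database search (protein query vs
six-frame DNA, and by role-swapping, DNA candidate vs protein reference)
fully offline:

* **Translation** uses the bacterial/archaeal genetic code (table 11);
  stops are rendered `*`, partial terminal codons dropped. Residues outside
  the BLOSUM62 alphabet (from ambiguous bases) become `X`, which scores as
  a universal mismatch — no information is fabricated from ambiguity codes.
* **Alignment** is exact affine-gap Smith–Waterman (Biopython's
  `PairwiseAligner`, local mode), BLOSUM62 with BLAST-style gap cost
  `11 + k` for a gap of length k. No heuristic seeding, banding or X-drop:
  at desk scale, exactness is cheaper than the complexity of a heuristic.
  Co-optimal alignments are disambiguated deterministically (longer
  alignment, then smaller subject start, then smaller query start).
* **Statistics** use the gapped Karlin–Altschul parameters for these
  costs (λ=0.267, K=0.041): `E = K·m·n·exp(−λS)` with m the query length
  and n the frame length in residues; NCBI-style bit scores
  `(λS − ln K)/ln 2`, so the tail law reads `P(bit ≥ s) ≈ m·n·2^(−s)`.
  A seeded shuffle test verifies the empirical tail stays within a factor
  of 3 of this law. The default cutoff, `E ≤ 1e-20`, is deliberately
  permissive: relatives of known IEPs score far below it, and the later
  stages — not search stringency — remove the non-group-II RTs it admits.
* **Prescreen** (performance): before the exact DP, each query/frame pair
  is screened with a bit-vector infix edit distance (edlib); pairs with
  distance > 0.62·m are skipped. The threshold sits in a wide empirical
  gulf: unrelated protein/frame pairs measure ≈0.76·m, related pairs
  (≥55% identity, even half-length truncations) ≤0.5·m. Very short
  fragments (<~25% of the query) could in principle be lost; the prescreen
  is a flag (`prescreen=False` recovers the exhaustive search).
* **Pooling**: HSPs from all queries merge into unique candidate loci when
  their nucleotide intervals overlap by ≥1 nt on the same
  (accession, strand); bookended intervals stay separate. Frames are not
  reconciled — a locus records every supporting query and frame.
* Repeated HSPs per frame (twintrons, frameshift halves) are recovered by
  masking each aligned subject segment with `X` and realigning, up to 3
  HSPs per frame.

## Screening rules

The RT verdict and the class assignment are both top-three counting rules
over a ranked match list (E-value, then raw score, then reference id — so
results never depend on database input order). A "probable" RT verdict
needs all top three matches to be group II introns (the count is a config
knob); with fewer than three references hit, the available ranks are used
and "probable" is unreachable — a conservative reading of the rule for
degenerate databases. Class CL1/CL2 reference subclasses collapse onto CL
for assignment; the subclass is kept as metadata.

## Domain inventory and ORF verification

Each reference IEP designates one conserved residue per domain
(0–7, X, optionally En) as a proxy. A domain counts once per alignment in
which its proxy position falls inside an aligned (non-gap) column; the
candidate residue need not be identical. Expected domains are
per-reference metadata, so classes without En are not falsely "missing".

ORF intactness requires, against the closest curated relative: exactly one
HSP (frameshifts split alignments across frames), no `*` inside the
aligned candidate frame, no gap run longer than 2 codons on either side
(a strict "no insertions" rule would reject natural 1-codon indels), and
coverage of ≥95% of the relative's domain 0→X span.

Start-codon selection scans ATG/GTG/TTG in frame within ±45 nt of the
position aligned to the relative's start. Each candidate start scores:
a displacement penalty (0.5 per codon), +2 for matching the relative's
annotated start codon, plus a Shine–Dalgarno score — the best log₂-odds of
the AGGAGG position-weight matrix (consensus probability 0.85 vs uniform
background) over spacers of 5–13 nt, floored at 0 so an absent SD is
neutral rather than punitive. A full SD match contributes ≈10.6 bits and
dominates, which is the intended behavior: ribosome-binding evidence
outweighs small alignment displacements.

## Boundary profiles and scanning

Per class and side, a profile holds one emission distribution per aligned
training column (Laplace pseudocount 1). Scanning scores every window
offset with two algorithms over the *same* parameterization — a glocal
profile match allowing up to ±3 nt of insertion/deletion drift, with path
weights log 0.90 per match step and log 0.05 per indel step:

* scorer A: Viterbi (max over paths);
* scorer B: Forward (log-sum-exp over the same paths), hence B ≥ A at
  every offset by construction.

Each scorer is z-scored against its own background (1000 seeded random
windows), and `best_score = max(z_A, z_B)`. Tiers: high ≥6, medium ≥4,
low ≥2.5. Peaks are kept by non-maximum suppression (one per profile
length), and each peak's reported position is re-anchored on the local
*ungapped* argmax within the drift slack — the gapped optimum can sit 1–2
nt off the motif when its best path opens with an indel.

A consequence of per-offset z-scoring: the achievable z of a perfect match
is ≈√(3·n) for n informative columns, so reaching the high tier reliably
requires ≥15 informative columns. Boundary profiles are therefore trained
on the boundary consensus *plus conserved interior context* (5 nt beyond
the 5' consensus, 10 nt before the 3' consensus) — biologically
reasonable, since the 5' consensus continues into the conserved DI stem
and the 3' terminus abuts the highly conserved domains V/VI. Profile
lengths end up at 18–22 columns. Short, heavily degenerate profiles
(including a bare 10–12 column 3' consensus) cannot clear the high tier —
this mirrors the real difficulty of placing 3' boundaries from sequence
alone.

At the default low threshold (z ≥ 2.5), ~0.6% of random offsets qualify,
so any window of a few hundred nt will carry low-tier background
candidates; "no boundary" judgments are meaningful at the medium tier and
above, and resolution defaults to the high tier.

**Resolution**: a plausible 5' candidate lies upstream of the ORF, a
plausible 3' candidate downstream; the pair must be ordered and span
400–8000 nt (bracketing known intron sizes) with the ORF strictly inside.
Exactly one plausible candidate per side yields the intron call; anything
else is ambiguous, with reasons recorded. An optional fallback
(`admit_medium_low`) admits the single best medium/low candidate on a side
that lacks a high-tier one — trading precision for recall, mirroring the
high-only vs all-tier operating points. Unclassified/undefined candidates
are scanned with the profiles of all classes and the merged candidate list
is ranked by calibrated score; when the two scorers' top positions
disagree, both surface in the report rather than being silently
reconciled.

## Redundancy reduction

Per class, the IEP region from the domain-0 proxy to the domain-X proxy is
excised (mapped onto each candidate through its reference alignment) and
aligned with MAFFT. Pairwise distances are JTT maximum-likelihood
estimates: the rate matrix is built from the Jones–Taylor–Thornton
exchangeabilities and equilibrium frequencies, normalized to one expected
substitution/site; the likelihood `Σ N_ab·log(π_a P_ab(t))` over pairwise
comparable columns (gaps excluded) is maximized over t by bounded 1-D
optimization on an eigendecomposition of the rate matrix. Agreement with
an independent grid-search oracle is ≤1e-3 and with R phangorn's
`dist.ml(model="JTT")` to five decimals.

Groups are single-linkage connected components of the graph with edges
`d < 0.061` (a pairwise-link criterion; under JTT, 95% identity in 400
residues measures ≈0.052, so the 0.061 threshold includes it with margin).
The prototype is the longest intact member (ties by id) — the selection
criterion is a config choice, since "representative" is otherwise
unspecified — plus one prototype per distinct species in the group, so
cross-species redundancy is preserved in the non-redundant output.

## Synthetic data: what it emulates, and what it does not

The generator (`groupii.fixtures`) is a pure function of its seed and
produces: per class an ancestral IEP (length 430 aa, residues drawn from
JTT frequencies), three curated relatives and three RT-database entries at
10% divergence, boundary consensus strings (class C uses the printed
GUNYGCCNRGCAUGG / CCUACYCGAU; other classes generated with the generic
GTGYG/…AY anchors and comparable degeneracy), and decoy RT families
(retron/DGR/CRISPR-RT) at 35% divergence from intron ancestors. Mock
genomes plant, one element per 11 kb record with ≥3.1 kb margins and
random strand: 5 singleton introns per class, identity clusters (sizes
3 and 2 at 95% identity, the first spanning two species), and 25 decoys
(6 truncated, 5 frameshifted, 5 premature-stop, 5 non-group-II RT,
4 twintrons). The divergence scales put within-class relatives at ~80%
pairwise identity (well clear of the 95% grouping threshold) while decoy
families rank above group II references for decoys and below them for true
introns.

The mutation model is substitution-only (no indels except the designed
frameshifts), so identity targets are exact and truth coordinates never
shift. Boundary motifs are planted unmutated by default; a
`boundary_mutation_rate` knob (0.10 in the noisy test condition)
substitutes motif columns per instance. Fillers are uniform random DNA.

Consequently, passing tests show that the machinery is correct under
clean, well-separated conditions; they do not show robustness to real
ribozyme variation: no RNA secondary structure, no indel divergence in
IEPs, no compositional bias, no 5'-inserted CL1 variants or class B 3'
extensions (known failure modes of profile-based boundary calling), no
ORF-less or LAGLIDADG-encoding introns. The frameshifted decoys are
designed to exit at the ORF stage with multiple HSPs; occasionally the two
HSPs both cover a domain proxy and the candidate exits one stage earlier
as "extra domains" — either way it is excluded.

## Problem sizes and determinism

The default suite (70 records × 11 kb, 45 introns + 25 decoys, 33-entry RT
database, 27 curated IEPs) runs end to end in about a minute on one core;
reference-bundle generation with self-consistency validation adds ~30 s.
These sizes were chosen as the smallest that exercise every rule
(top-three counting, subclass choice, cross-species prototypes, every
decoy kind) with non-trivial multiplicity.

All randomness flows from explicit seeds (numpy `default_rng`); profile
calibration seeds derive from class/side names. Pipeline state is
serialized as sorted-key JSON plus TSV/FASTA, GenBank output uses a fixed
date, and two runs with the same seed and configuration produce
hash-identical storage trees — asserted by test.

## Known limitations

* Boundary tiers are Gaussian z-scores against a background whose tail is
  not exactly Gaussian; tier boundaries are operating points, not
  calibrated probabilities.
* The Karlin–Altschul parameters are the standard gapped BLOSUM62 values;
  no composition-based adjustment or finite-size edge correction is
  applied.
* `ml_distance` assumes JTT with equal rates across sites (no +Γ); the
  model is pluggable in principle but JTT is the only packaged matrix.
* The prescreen can skip legitimate hits shorter than ~25% of the query;
  disable it for exhaustive searches.
* Remote sequence retrieval is out of scope: the pipeline operates on
  local GenBank/FASTA files only.
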