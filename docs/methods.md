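# Methods

## Scope and model

`paralogpocket` analyses how tandem chemoreceptor paralogs diverge after
duplication, along two arms: comparative genomics of the gene family and
interaction geometry of ligand-bound sensor domains.  Both arms are
validated against a synthetic-data layer whose generators plant known truth,
so the package's claims are statements about procedures — filtering,
clustering, inference, geometric classification — not about any particular
downloaded corpus.

## Sequence comparison and homolog filtering

Pairwise alignments are full-length global (Needleman–Wunsch) with BLOSUM62
scores and affine gaps (first gap residue −11, extensions −1), the regime
appropriate to full-length receptor homologs where hits are only kept at
query coverage ≥ 90%.  A local (Smith–Waterman) mode is available behind the
same interface.  Identity is defined over residue–residue columns only, and
coverage as the fraction of query residues aligned opposite a subject
residue; both conventions are stated because reported identity figures in
the literature rarely define their denominator.  E-value filtering is
deliberately omitted: Karlin–Altschul statistics require a database-scale
null model, whereas identity and coverage are database-size-free and are the
operative filters here.  Correctness of the aligner configuration is pinned
by an exhaustive Gotoh dynamic-programming oracle on random ≤30-mers.

Orthology uses the bidirectional-best-hit rule with deterministic
tie-breaking (lexicographic id at equal score).  BBH is knowingly fallible
when a genome has lost its co-ortholog; the analysis scripts surface the
concordance against simulation truth rather than hiding it.

## Redundancy reduction

Two genomes merge when (a) their homolog counts match and a one-to-one
matching of their homolog sets exists in which every pair is (b) 100% query
coverage in both directions and (c) 100% identical.  The matching is greedy
by alignment score (the condition is near-degenerate at 100%/100%, so the
greedy optimum is the optimum); clusters are the transitive closure of the
pairwise relation, and missing hits count as non-identical.  The
representative is the member with the highest assembly level
(contig < scaffold < chromosome < complete), ties to the smallest genome id.
Reduction is idempotent and order-free; both properties are tested.

## Phyletic profiling and birth-node inference

Profiles are copy-count matrices (families × genome-tree leaves), with
pseudogenes excluded from presence but kept flagged.  Birth nodes assume a
single gain (Dollo parsimony): the family originates at the MRCA of its
presence leaves, and the implied losses are the minimum number of deleted
subtrees below that node covering every absence — computed as the number of
maximal all-absent subtrees, and verified against exhaustive subset
enumeration on ≤12-leaf trees.  Parsimony minima are lower bounds on the
true loss count (sibling losses merge into one inferred event); on the
simulator at the default loss rate the bound is tight in over 80% of
replicates, which is measured, not assumed.  Duplications are attributed
leaf-wise as Σ max(0, count−1), and the paralog burden of a corpus is
summarized as the fraction of genomes whose total copy count is ≥ 2.

Guide trees come from neighbor joining (dendropy) on distances corrected for
multiple hits with the 20-state formula d = −(19/20) ln(1 − 20p/19),
midpoint-rooted.  NJ recovers additive matrices exactly; maximum-likelihood
inference is out of scope because no claim here depends on branch-length
optimality.

## Conservation statistics

Column information content is IC = log₂ 20 − H over gap-excluded residue
frequencies; no small-sample correction is applied by default (determinism
and transparency at typical cluster sizes), with a Miller–Madow-style
correction behind a flag.  Columns gapped in > 50% of a cluster are excluded
from motif windows.  An HCR is a maximal merged run of sliding windows
(default 10 columns) whose mean IC ≥ 2.5 bits in at least
n_clusters − max_exceptions clusters (default one exception, matching the
observation that a single receptor cluster with a different ligand
repertoire lacks the motif); the clusters failing over the merged region
are reported as the exceptions.  Window smearing widens a detected region
by at most window − 1 columns on either side of the underlying conserved
block, which the tests account for explicitly.  Domain-partitioned identity
takes user-supplied domain intervals in reference-sequence coordinates —
boundaries for real receptors are an input, and defaults ship only for the
synthetic data.

## Interaction criteria

* Contact: residue ↔ ligand minimum heavy-atom distance < 5 Å.  Heavy atoms
  only, for consistency between hydrogen-free crystal structures and
  hydrogenated ensembles.
* Hydrogen bond, `md` mode (explicit hydrogens): donor–acceptor < 3 Å and
  donor–hydrogen···acceptor deviation from linearity ≤ 20° — the standard
  trajectory-analysis convention.  Calling it without hydrogens raises an
  error directing to `xray` mode.
* Hydrogen bond, `xray` mode (hydrogen-free): donor/acceptor typing from
  residue/atom-name dictionaries and D–A ≤ 3.35 Å with no angle term.
  Because donation direction is unresolvable without hydrogens, each
  physical atom pair is counted once.
* Hydrophobic: carbon–carbon pairs < 4 Å where neither carbon is covalently
  bonded (distance-inferred at ≤ 1.9 Å) to N/O/S.
* Waters are excluded from hydrogen-bond networks entirely.
* Pocket occupancy per chain: the target ligand inside at ≥ 10 pocket-residue
  contacts, at the entrance at ≥ 1, a different het group inside by the same
  rule, else empty.  The inside threshold and the 8 Å release distance are
  calibration constants exposed in configuration and recorded in run
  provenance.
* Ligand release: the first frame from which the ligand stays beyond 8 Å of
  every pocket residue for the rest of the ensemble; transient excursions do
  not count.

Altloc policy keeps blank/'A' locations; occupancy-weighted handling is not
implemented.  All geometric decisions are pinned to exhaustive pairwise
oracles on small fixtures.

## Synthetic data: what it emulates and what it does not

The family simulator evolves one founding gene down a genome tree under
uniform residue replacement with per-segment rate scaling: the sensory
segment runs 8× the signaling rate, and planted motif columns run 100×
slower than the rest of the sensory segment (the spec of the regime only
bounds this at ≥ 10×; 100× reproduces a motif that stays effectively intact
across the tree, which is the observed behaviour being emulated).
Duplication copies the whole gene into the same genome, founding a new
family whose true birth node is recorded; loss removes a copy;
pseudogenization flags it heritably, and flagged copies are excluded from
presence calls.  The demo conditions are an 8-genome balanced tree,
180-residue proteins, base rate 0.6 substitutions/site-unit, duplication
0.5 and loss 0.1 per branch-length unit, pseudogenization 0.02 per copy per
branch — duplication/loss rates are free parameters of the regime (no
published values exist to pin them) chosen so a typical replicate shows a
handful of birth and loss events on an 8-genome tree.  Under these
conditions absolute identity levels are lower than a real closely-related
paralog trio would show (the ordering and the contrast between domains, not
the absolute level, is what downstream statistics consume).  Sequences are
emitted ungapped, so "alignment" is the identity map — indel evolution, codon
structure, substitution-matrix realism and rate variation beyond the
two-segment contrast are all absent, which is why passing tests certify the
inference machinery, not field performance on real corpora.

The pocket generator plants exact geometries: shell residues at requested
minimum distances (solved by bisection on the placement radius, reproduced
within 0.01 Å), donor residues with two hydroxyl arms so per-frame bond
counts of 0/1/2 are constructible, ligand-amino acceptors placed on the
existing amino-hydrogen geometry, and apolar pairs at requested separations.
Residues are placed on well-spread directions with incremental steric
checking (≥ 1.5 Å between groups) and alternative-direction retries;
infeasible requests raise.  Every emitted structure is re-measured by the
detection code before being returned.  Trajectories are multi-model PDB
ensembles (binary trajectory formats are avoided deliberately): contact
residues translate radially in/out with Bernoulli per-frame states, H-bond
counts follow floor(rate) + Bernoulli(fractional part) — a rate of 1.5
yields the ~150% occupancy signature of a residue forming two bonds half the
time — and a release frame moves the ligand 60 Å out permanently.  The
fixtures have no force-field realism: no thermal jitter of non-controlled
atoms, no rotamers, no solvent.

## Numerical and reproducibility choices

All randomness flows from integer seeds through `numpy.random.default_rng`;
identical seeds give byte-identical outputs (tested).  Tie-breaks are
lexicographic everywhere.  Geometry solves use Brent bisection to 1e-9–1e-12
tolerances; re-measurement tolerances are 0.01 Å and 0.5°.  Degenerate
inputs fail loudly: empty trees, all-gap columns, absent genomes, md-mode
H-bond detection without hydrogens, trajectories referencing unknown
residues.  Pipeline runs write a provenance record with the package version,
seed, every threshold, and input digests; reruns are bit-identical.

## Problem sizes

The shipped study conditions are deliberately desk-scale: 8-genome trees,
180-residue proteins, 50-frame ensembles, ≤ 500-atom fixtures, and 100-seed
replicate studies for the statistical claims (rate-contrast recovery, HCR
localization ≥ 95/100, contact-fraction recovery within 3·√(p(1−p)/n)).
These sizes make every statistical property measurable in seconds while
leaving the estimators in the regime where binomial noise is visible rather
than negligible — a 50-frame ensemble has a 3σ band of ±0.17 on a planted
fraction of 0.8, and single seeds landing near that edge are expected and
reported as such.

## Known limitations

* BBH orthology degrades when co-orthologs are lost; concordance against
  truth is reported, not patched.
* Dollo inference underestimates losses when sibling lineages lose
  independently.
* The redundancy rule is exact-identity only; sub-100% clustering
  (CD-HIT-style) is out of scope.
* X-ray-mode hydrogen-bond typing is dictionary-based and will miss
  nonstandard chemistry; the deposited-structure battery exists precisely to
  check those counts when the public entries are staged under `data/`.
* Master alignments across clusters are required input; no progressive
  aligner is bundled.
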