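# paralogpocket

Evolutionary and structural analysis of paralogous chemoreceptor
ligand-binding domains.

Bacteria sense their chemical surroundings through large repertoires of
methyl-accepting chemotaxis proteins (MCPs).  Families of tandem paralogs —
the amino-acid sensors PctA/PctB/PctC of *Pseudomonas aeruginosa* are the
motivating case — arise by gene duplication and then diverge almost entirely
within the periplasmic sensory (dCache_1) domain, while the cytosolic
signaling domain stays nearly frozen and a short amino-acid-binding motif
inside the sensor stays intact.  `paralogpocket` implements both arms of
that analysis for anyone studying how such paralogs subfunctionalize:

* **comparative genomics** — all-vs-all homolog search with
  identity/coverage filtering (≥30% / ≥90%), redundancy-reduction
  clustering of sequence-identical genomes, bidirectional-best-hit (BBH)
  orthology, phyletic profiles on a genome tree, single-gain (Dollo)
  birth-node inference with minimal implied losses, neighbor-joining guide
  trees, domain-partitioned divergence, per-cluster sequence logos and
  detection of highly conserved regions (HCRs) shared by almost all
  clusters;
* **structural analysis** — ligand contacts at 5 Å, hydrogen bonds
  (donor–acceptor < 3 Å with ≤ 20° deviation from linearity given explicit
  hydrogens, or a 3.35 Å distance-only rule for hydrogen-free
  crystallographic models), hydrophobic carbon pairs at 4 Å, per-residue
  occupancy frequencies over multi-model ensembles (above 100% when a
  residue holds two simultaneous bonds), pocket-occupancy classification per
  chain, ligand-release detection, and cross-paralog mapping of binding
  residues through a shared alignment;
* **synthetic data** — a gene-family simulator (duplication / loss /
  pseudogenization on a genome tree, 8× sensory rate contrast, near-invariant
  planted motif) and a pocket/trajectory generator that plants exact contact,
  hydrogen-bond and hydrophobic geometries, so every stage is testable
  offline against construction truth.

## Core quantities

For an alignment column with gap-excluded residue frequencies *p₁…p₂₀*, the
information content is IC = log₂ 20 − H(p) bits, with H the Shannon entropy;
an HCR is a maximal run of windows whose mean IC ≥ 2.5 bits in all but at
most one cluster.  A family's birth node under Dollo parsimony is the MRCA
of its presence leaves; implied losses are the minimum number of pruned
subtrees explaining the absences.  Ensemble statistics are per-residue
fractions over frames: contact fraction = frames within 5 Å / frames,
H-bond occupancy (%) = 100 × bonds formed / frames.

## Worked example

```
$ python analysis/01_simulate_family.py
simulated 15 sequences (1 pseudogenes) across 8 genomes
events on branches: {'duplication': 3, 'pseudogenization': 1}
families born: ['F0', 'F1', 'F2', 'F3'] at nodes ['N0', 'N4', 'N2', 'G5']

$ python analysis/04_conservation_logos.py
mean pairwise identity: sensory 24.2%, signaling 73.9% (the sensory segment evolves ~8x faster)
HCR at alignment columns 53-72: covers 100% of the planted motif, absent from ['cluster5_nomotif']

$ python analysis/05_structure_contacts.py
50-frame ensemble:
  residue 1 contact fraction 0.94 (planted 0.80)
  residue 2 contact fraction 0.42 (planted 0.40)
  residue 4 H-bond occupancy 150% (planted rate 1.5 bonds/frame -> ~150%: two simultaneous bonds half the time)
  ligand release detected at frame 30 (planted 30)
seven-chain assembly occupancy: {'A': 'ligand-inside', 'B': 'ligand-inside', 'C': 'ligand-at-entrance',
 'D': 'ligand-at-entrance', 'E': 'ligand-at-entrance', 'F': 'other-molecule', 'G': 'empty'}
```

The identity split shows the sensory/signaling rate contrast the simulator
plants; the HCR call localizes the planted binding motif and names the one
cluster lacking it; the ensemble numbers recover the planted per-frame
statistics within binomial noise (residue 1's 0.94 vs 0.80 is within the
3σ band at 50 frames), and the seven-chain assembly is classified into two
ligand-inside chains, three at the pocket entrance, one occupied by a
different small molecule and one empty.

The same stages are scriptable (`paralogpocket run --config config.yaml`,
`paralogpocket simulate family ...`, `paralogpocket contacts ...`) or
importable from `paralogpocket.*`.

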