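# Methods

This note documents the models and procedures implemented in `cypscout`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Problem setting

Bacterial cytochrome P450s (BacCYPs) are soluble heme monooxygenases whose
substrate range spans fatty acids, terpenoids, macrolides, and polycyclic
aromatics. The overwhelming majority of annotated BacCYP sequences carry no
substrate annotation. `cypscout` implements a desk-scale pipeline that
combines four independent, individually weak information sources into a
ranked substrate-group prediction: chemical clustering of known substrates,
phylogenetic placement of the query sequence, the reactions annotated on
the query gene's genomic neighbours, and docking-score statistics.

## Compound space (`chemspace`)

Compounds are binary fingerprints compared with the Tanimoto index
TI(a, b) = |a ∩ b| / |a ∪ b|. When SMILES are supplied, circular (Morgan)
fingerprints of radius 2 and 2048 bits are computed via RDKit — the
community-default parameterisation, chosen for comparability; RDKit is an
optional dependency and every downstream step operates on plain bit sets.

Substrate groups are built by sphere-exclusion (Butina) clustering,
re-implemented rather than delegated: each compound's neighbourhood is the
set of compounds at TI ≥ cutoff; the unassigned compound with the most
unassigned neighbours repeatedly becomes a centroid and absorbs its
neighbourhood. Ties on the neighbour count break by lexicographic id so
the partition is deterministic. The cutoff is selected by scanning
candidates and minimising the fraction of unclustered compounds subject to
a floor (default 2) on the number of multi-member clusters; ties prefer
the larger cutoff (tighter clusters). The balancing objective itself is a
design choice — the goal it operationalises is a good cluster count with
few singletons.

A caution discovered during testing: the cluster count of sphere-exclusion
is *not* monotone in the cutoff for arbitrary similarity matrices. Raising
the cutoff can reorder the greedy centroid selection so that one sphere
absorbs compounds that two spheres previously split. Monotonicity holds on
libraries with clear group separation, which is the operating regime here;
the test suite asserts it only there.

## Phylogenetic grouping (`phylo`)

Trees arrive with branch lengths in substitutions/site (tree inference
itself is out of scope). Groups are obtained by complete-linkage
hierarchical clustering of the cophenetic distance matrix (leaf-to-leaf
path lengths, via dendropy). The cut is chosen by scanning k = 2..kmax and
maximising the number of *major* groups — groups holding ≥ 1% of leaves —
with ties resolved to the smallest k (parsimony). Complete linkage was
chosen to produce compact groups matching the conventions of the R
workflow this rule originates from.

New sequences are assigned to groups by a 3-mer nearest-centroid
classifier: cosine similarity between the query's overlapping 3-mer count
profile and each group's mean profile, reporting the best group, its score
and the margin to the runner-up. Profile HMMs would be the heavier
alternative; the k-mer classifier needs no external builds and recovers
planted clades essentially perfectly at the benchmark divergence (5%
within-clade, 30% between-clade ancestors).

The family motif scanner covers the heme-binding signature
F-[G/S]-X-G-X-[H/R]-X-C-X-G (terminal G relaxed to [G/A] for the group
that carries alanine), E-X-X-R, the proton-relay motif
[A/G]-G-X-[D/E]-T-[T/S], and [N/H]-R-D-P. X slots accept any standard
residue plus the ambiguity codes B/Z/X; literal slots accept only their
stated letters. Hits report positions local to the supplied sequence —
the published motif coordinates live in an unpublished alignment numbering
and cannot be reproduced. Group-diagnostic residues (e.g. group L:
P131, L132, P133, I137, P144, R149, W155, S156) are checked against a
caller-supplied mapping into domain numbering; groups with no diagnostics
score 1.0 by convention and are flagged.

Pairwise identity uses a global alignment (match +1, mismatch 0, gap −1)
with terminal-gap columns excluded from the denominator, so domain
fragments are not penalised for overhang. The identity-vs-substrate-TI
analysis stratifies protein pairs into all / same-group / >70%-identity
(strict inequality at the boundary).

## Genomic context (`context`)

Annotations come from local GFF3 or TSV tables plus a gene → compound
links table (a stand-in for live pathway-database queries; an adapter can
be plugged in). Neighbours of a target are genes on the same contig whose
intervening-base gap (overlap/abutment = 0) is within the threshold,
inclusive — the default 2000 bp matches the expanded search window.
Strand does not affect eligibility (operons are usually strand-coherent,
but filtering on it would discard informative divergent neighbours); it is
reported for downstream use. The nearest gene on each side is flagged
adjacent.

Candidates are the union of neighbour substrates and products. With
reference compounds available they rank by best TI against the references;
otherwise by adjacency and gap. At equal rank a neighbour's *product*
precedes its substrate: in an operon the upstream enzyme's product is the
likelier P450 substrate. Recovery counts a target as solved when its
rank-1 candidate reaches TI ≥ 0.85 against the truth (near-identity,
configurable), over the denominator of targets that yielded any candidate
at all — uninformative genomes are excluded rather than counted as
failures.

## Docking statistics (`docking`)

Docking engines run externally; this module emits their configuration and
consumes their score tables. Grid boxes are cubic: 40 Å edge for ligands
under 35 atoms, 60 Å from 35 up (the boundary itself is unaddressed in the
protocol; the permissive box is chosen), spacing 0.375 Å, centre 10 Å from
the heme centre along a caller-supplied unit normal (a helper fits the
normal to the four porphyrin nitrogens by least squares). Bias
specifications accept exactly one heme-coordination reward plus at most
three additional site rewards, all ≤ 0 kcal/mol. Assay records are
filtered at pchembl strictly greater than 6.

Per receptor, the ligand panel's best-pose energies and pose populations
(best-cluster run counts, normalised to run fractions for comparability
across panels) are converted to Z-scores with the sample standard
deviation (ddof = 1). Binders are called relative to the receptor's known
true ligand: a ligand is a binder when its energy Z-score is at most
0.9 × the true positive's (more negative) *and* its population Z-score is
at least 0.9 × the true positive's. The per-axis conjunction is one of
three defensible readings of "above 0.9 of the true-positive Z-score"; the
product and Euclidean-norm variants are exposed as options. A panel whose
true positive is not itself in the favourable quadrant is flagged
degenerate; the true positive is a binder by definition. Selectivity is
summarised as a receptor × ligand-group binder-count matrix; promiscuity
of a receptor is its number of groups with at least one binder.

## Structure evaluation (`structure`)

Superposition is least-squares rigid (Kabsch via SVD-based rotation
alignment), proper rotations only — reflections are asserted away. The
RMSD report gives the whole-domain and CA metrics after their own optimal
fits, but evaluates active-site RMSD on the heavy atoms of the listed
residues *in the frame of the CA superposition*: re-fitting the pocket
alone would hide exactly the placement error this metric is meant to
expose. The 24-residue active-site list is a required input (its
composition is structure-specific). Modelling templates tier by
phylogenetic distance — [0, 2] short, (2, 4] mid, > 4 long, boundaries
closed on the right so the touching published ranges partition cleanly —
and external model-quality scores (statistical potentials, predicted
confidence) select the best replica via a direction flag.

## Evidence integration (`integrate`)

The workflow runs phylogeny → context → docking, skipping absent resources
with explicit stage records. Combination is ordinal, not a fitted score:
the sources are incommensurable and the protocol combines them
qualitatively. Candidate substrate groups are tiered
context∧docking > docking-only > context-only > phylogeny-only, with ties
broken by docking margin (the smaller of the two Z-margin ratios), then
context TI. The phylogenetic prior (ligand groups seen in the assigned
group) never filters docking or context output — sequence similarity is
the least informative source and is treated as such.

## Synthetic worlds (`synth`)

One seed generates one world; every generator asserts its own design
targets after generation, so downstream benchmarks are self-validating.

- **Compounds** — 17 groups × 8 members, 512-bit fingerprints. Each group
  has a 64-bit scaffold; members swap r scaffold bits for random off bits,
  with r derived from the midpoint of the intra-TI target range
  (0.6–0.8): min intra-TI ≥ (64 − 2r)/(64 + 2r) deterministically, while
  cross-group overlap stays near the 64/512 background (mean inter-TI
  ≈ 0.07 ≪ the 0.35 ceiling). The design cutoff 0.45 sits between the
  two regimes.
- **Tree/sequences** — 6 clades × 20 leaves from per-clade ancestors (30%
  diverged from a shared root), leaves and held-out queries at 5%
  divergence, length 300.
- **Genomes** — 200 genomes; each plants one producer gene within
  50–800 bp of the target whose product is the true substrate (or, 20% of
  the time, a ≥ 0.9-TI analog), among 6 decoy genes with random
  cross-group compounds placed farther out. With 2% probability per
  genome one decoy lands closer than the producer — irreducible noise of
  operon inference. A null mode drops the producers for base-rate
  controls.
- **Docking** — 15 receptors × the 35-ligand panel (two per group, one
  group with three) = 525 records, 100 runs each. Decoys: energy
  ~ N(−6, 1) kcal/mol, population ~ Binomial(100, 0.2). Planted binders:
  energy offset −3 kcal/mol with sd 0.1, population offset +40 runs with
  sd 1 — true substrates dock reproducibly into one deep pose while
  decoys scatter; the tight binder spread is what makes the
  0.9-of-true-positive rule's 10% slack sufficient, as an
  error-propagation estimate of the rule predicts. Three receptors are
  planted promiscuous (binders from 6 groups), mirroring the observed
  promiscuity regime.
- **Structures** — 200-residue CA traces (3.8 Å steps); models are rigid
  motions of the reference plus optional Gaussian noise (default sd
  0.5 Å per coordinate), whole-chain or active-site-only. One-sided
  isotropic noise gives E[RMSD] ≈ σ√3, which the Monte-Carlo tests
  confirm within 10%.

**What the synthetic worlds do not emulate:** real chemistry (fingerprints
are abstract bit sets, not molecules), realistic molecular evolution
(uniform point substitutions, no indels or rate heterogeneity), operon
transcriptional structure, or docking physics (scores are draws from the
assumed two-population model). Passing the benchmarks shows the *pipeline
machinery* recovers planted signals of the assumed shape at realistic
effect sizes; it does not validate the biological assumptions themselves
(that operon neighbours produce P450 substrates, or that true binders are
jointly extreme in energy and population) — those come from the domain.

## Problem sizes and numerics

Benchmarks run at desk scale: 136-compound libraries, 120-leaf trees, 200
genomes, 525 docking records, 60 end-to-end queries — sizes at which the
planted-recovery statistics are stable yet the full suite completes in
seconds. Degenerate inputs are handled explicitly rather than silently:
both-empty fingerprints give TI 0 with a warning; zero-spread Z-score
panels yield all-zero scores with a flag; missing branch lengths, absent
true positives, and collinear point sets raise. Ties everywhere break
deterministically (lexicographic ids, smallest k, larger cutoff).

## Known limitations

- Group assignment is a k-mer classifier, not a placement into the actual
  tree; divergent queries beyond the reference clades degrade gracefully
  but are not flagged as outliers.
- Motif positions are query-local; mapping to domain numbering is the
  caller's responsibility, as is the active-site residue list.
- The evidence tiers are a fixed convention; no quantitative rule merges
  conflicting context and docking evidence.
- The binder-calling rule anchors on a known true ligand; receptors
  without one can only use the degenerate-panel path.
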