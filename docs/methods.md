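# Methods

## Scope and data model

All algorithms operate on gene adjacency: a genome is, per chromosome, an
ordered list of oriented genes (0-based integer ranks internally, 1-based in
files; strand ±1).  Base-pair coordinates are read and written but never
used in computation.  Centromeres are gap indices (number of genes on the
left arm) and matter only to the simulator's fusion/fission operators.
Chromosome-anchored input is required; unanchored scaffolds would bias both
karyotype and adjacency inference and are not supported.

## Ancestral gene content (Dollo parsimony)

Gene families are the unit of ancestral identity: one ancestral gene per
family per node, named `<family>@<node>`.  A family is present at a node
iff the node lies on the minimal spanning subtree of the leaves carrying
members — the unique minimal-loss single-origin assignment (verified in the
tests by exhaustive enumeration over presence sets for all small trees).
Consequences to be aware of:

- "Absence" is family-lineage absence.  Post-polyploidy copy multiplicity
  is *not* inferred here; it enters only through ortholog maps.
- A true ancestral gene whose family survives nowhere in the analysis set
  (e.g. only in an outgroup that then loses it, or lost independently in
  both descendant lineages) is invisible to any conservation-based method.
  Evaluation therefore projects the true ancestor onto the inferable
  namespace before scoring order (below).
- Gains above the root cannot be placed; they are reported in a synthetic
  `origin` row of the gain/loss table.

## CAR reconstruction

Informative pairs for ancestor *A* are exactly the leaf pairs whose tree
path contains *A*.  Both genomes of a pair are reduced to genes mapping to
*A*'s content (outgroup members of a family map through the same content
set); adjacencies are only formed within chromosomes, never across ends,
and with orientation required to be conserved up to joint reversal.  The
canonical form of an oriented adjacency is the lexicographically smaller of
`(u,su,v,sv)` and `(v,−sv,u,−su)`.  An adjacency counts once per
informative pair regardless of copy multiplicity: weights measure
phylogenetic, not copy-number, support.

Greedy linearization examines edges by (weight descending, canonical key
ascending) — the lexicographic tie-break makes the otherwise
non-deterministic greedy fully reproducible.  Every oriented adjacency
occupies one end ("side") of each incident gene; an edge is accepted iff
the side it needs is free at both endpoints and it does not close a cycle
(union–find).  Rejecting an edge whose side is occupied implements
"drop the lower-weight conflicting adjacency, keep both fragments", since
the occupying edge always sorted earlier.  Accepted edges form simple
paths; strands are propagated from the signatures, and each CAR is written
from its lexicographically smaller end.  The greedy is a 1/2-approximation
of the maximum-weight path cover, not an exact solver — deliberately so, as
the top-down weight ordering is the method being reproduced; the tests
check exact equivalence with an independent declarative implementation of
the acceptance rule over an exhaustive enumeration of small weighted
graphs, and the suite documents (as an expected-failure property) that even
on trees the greedy can be strictly suboptimal.

The contig round rewrites each reduced genome as oriented CAR tokens
(genes outside all CARs are dropped first, so isolated singletons do not
break a run; runs of one CAR collapse to a token oriented by the majority
direction of member positions, ties forward), accumulates conserved contig
adjacencies over the same pairs, linearizes with the same rule, and splices
chained CARs at gene level.

Scaffolding automates what is classically a manual step, so that results
are reproducible: CARs of at least `min_car_size` genes (default 50, the
conventional small-CAR cutoff) are grouped when their majority-chromosome
profiles agree in a majority of reference descendants, ordered and oriented
within a protochromosome by median descendant rank in the guide genome.
The guide defaults to the least-rearranged descendant, proxied by the
fewest CAR-token runs, and is configurable.  Protochromosome junctions are
scaffold-level joins without gene-level adjacency evidence; they are never
counted as adjacencies.

## Evaluation against simulated truth

Content precision/recall compare full gene sets.  Adjacency
precision/recall/F1 compare canonical oriented adjacency sets, with the
true ancestor projected onto the reconstruction's content namespace
(dropping truth genes outside it while preserving order).  This separates
"how well is the order of the inferable markers recovered" from "how much
content is inferable", which the content metrics report; without the
projection, unrecoverable genes would charge the order score for shortcut
adjacencies that are correct over the comparable marker set.  Genes wrongly
included by the reconstruction still count against adjacency precision.
Protochromosome grouping is scored separately as co-chromosome pair
concordance (Rand-index style, over genes placed by both karyotypes).

## Fractionation analysis

Windows are disjoint and consecutive (default 100 genes; the last window of
a chromosome may be short) — the literal reading of per-window counting; a
sliding variant is deliberately not the default.  Ortholog clusters are
built per extant chromosome with rank gaps ≤ 50 (default); two clusters on
one chromosome compete independently for the three labeled slots.  Labels
are assigned by descending retained count with ties broken by (chromosome
name, start rank), so `count(LF) ≥ count(MF1) ≥ count(MF2)` holds by
construction and is re-asserted.  Windows are labeled independently; label
flips of physically continuing regions (same chromosome, rank intervals
abutting within the gap threshold) between consecutive windows are reported
as dominance/sensitivity exchanges rather than smoothed away.

Ks/Ka use Nei–Gojobori counting with Jukes–Cantor correction: per-position
synonymous fractions averaged over the two sequences, substitutions to stop
codons counted as nonsynonymous (this convention reproduces the standard
worked examples and agrees with Biopython's NG86 to machine precision,
which the tests check), pathway averaging over all orders for
multi-substitution codons, and `valid=False` when ps or pn ≥ 3/4 (the
correction is undefined).  Maximum-likelihood (codeml-style) parity is not
promised; the estimator supports rank and ordering claims.

## The simulator

The simulator defines the study conditions; its defaults are the
conditions under which the acceptance checks run.

- Tree: the five-taxon Brassicaceae-like topology
  `(((At,Al)A1,Cr)ACK,(Br,Tp)PCK)ABK` with an outgroup, root age 27 my for
  ABK (speciation depths 7/13/12 my), all lengths multiplied by
  `time_scale` (desk-scale analyses use 0.2 so that runs finish in
  seconds at 2000 root genes).
- Root karyotype: 8 chromosomes × 250 genes, centromeres mid-chromosome.
- Rates per my: inversion 1.0 (geometric length, p = 0.2), reciprocal
  translocation 0.1, RTA fusion 0.05, fission 0.02, gene gain 20 and loss
  45 (absolute counts at the 2000-gene scale, echoing the observed
  loss-biased asymmetry).  Gains are 50 % novel insertions at a uniform
  locus and 50 % tandem duplications.  Events are Poisson per branch,
  placed uniformly in time; an event drawn for a state where it cannot
  apply (e.g. fusion with one chromosome) is resampled among applicable
  types and the resampling is logged.
- The RTA fusion operator is stylized: chromosome B's short arm is
  inverted, the fusion joins A to the inverted arm, and the minor product —
  B's centromere plus 0–2 pericentric genes — is deleted; the result is
  monocentric and the gene ledger balances exactly.
- Hexaploidy (on the Br branch, 40 % along it): three copies; MF1 and MF2
  exchange chromosome tails at breakpoints ≥ 100 genes apart (blocks at
  least window-sized, matching the "large block" character of observed
  dominance exchanges and making each breakpoint resolvable by 100-gene
  windows) before LF joins; each copy is then deleted independently with
  its **origin** subgenome's probability (defaults 0.2/0.45/0.6 for
  LF/MF1/MF2).  Dominance is modeled as a property of the progenitor
  block, not the receiving chromosome — that is precisely what makes an
  exchange observable as a retention flip along a continuous chromosome.
- Sequences (optional): random stop-free codon sequences at the root;
  per-branch Poisson substitution proposals (uniform base, stop-creating
  proposals rejected) at `subs_per_site_per_my` (default 0.01, 100
  codons).  Progenitor split offsets (LF 6 my, MF1/MF2 3 my before the
  merge) give the expected Ks ordering MF1–MF2 < LF–MF1 ≈ LF–MF2.  Genes
  born mid-branch accrue a full branch of divergence — a deliberate
  simplification that biases young genes slightly old and affects no
  ordering claim.
- Determinism: one numpy Generator stream; draw order is fixed (per-branch
  schedules in preorder, parameters at application time).  Within-run
  replay of the event log reproduces every extant genome exactly;
  cross-implementation bit-equality is not promised.

What the simulator does not emulate: transposable elements and repeats,
selection and codon bias, population-level polymorphism, unanchored
assemblies, and annotation error.  Passing tests therefore demonstrate
algorithmic correctness and statistical behavior under the generative
model, not robustness to real-data artifacts such as fragmented assemblies
or family-clustering noise.

## Numerical and degenerate-input choices

- All set iterations are sorted and all tie-breaks fixed, so reruns with
  one seed are byte-identical down to the output files.
- Empty reductions (no shared content) warn and return empty genomes; a
  window with no surviving region is flagged rather than dropped; empty
  connectivity classes report `None`, not 0; concordance over fewer than
  two shared placed genes is undefined (`None`).
- `read_gene_orders` sorts by start_bp with gene-id tie-break; duplicate
  gene ids and unknown strand tokens are hard errors with position
  information.
- Karyotype files flatten protochromosomes to gene lists; member-CAR
  boundaries are not serialized (write∘read∘write is byte-identical, and
  read-back equality holds at gene level).

## Known limitations

- Family-level Dollo content cannot represent ancestral copy number; tandem
  arrays collapse to one ancestral gene, and reconstruction metrics treat
  duplicate-family truth adjacencies accordingly.
- The ordered fraction is only weakly sensitive to the inversion rate at
  desk scale (the contig round heals most breakage); clear decreases
  appear from a few inversions per my upward.
- The scaffolding heuristic (majority profile + guide ordering) is a
  reproducible stand-in for expert curation, not a reimplementation of any
  particular manual scaffolding.
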