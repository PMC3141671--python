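# Methods

`dupetime` answers a gene-family question: for a cyclostome (lamprey) gene
whose position in a gnathostome gene tree is uncertain, did a designated
duplication event happen before or after the cyclostome–gnathostome
speciation? It does this by exhaustive constrained placement of the query
gene, likelihood weighting of the candidate topologies, and an event-timing
rule, plus an independent track of coding-sequence composition diagnostics
(GC3, ENc, RSCU, CA/WCA) that probe compositional explanations for
phylogenetic ambiguity. This note records the models, the defaults and the
numerical choices, and what the synthetic-data tests do and do not show.

## Backbone, placements and arrangements

The shipped backbone is the eight-gene gnathostome KCNA (shaker) family.
Six genes sit in two syntenic tri-gene clusters created by two tandem
duplications followed by one cluster-wide duplication; on the gene tree the
cluster duplication appears simultaneously as the three paralog-pair
cherries (KCNA1,2), (KCNA3,6), (KCNA5,10). Relationships among KCNA4, KCNA7
and the cluster genes are fixed; the three possible pairings among the
cherries are treated as equally likely, giving three fully binary
arrangements of the same leaf set.

A query gene is grafted onto every branch of every arrangement, including
the slot above the root. An n-leaf rooted binary backbone has 2n−2 branches
plus the root slot, so the KCNA backbone yields 15 positions per
arrangement and 45 candidate topologies in total. Grafting bisects the
chosen branch (halving its length; the pendant branch defaults to 0.1
substitutions/site before optimization) and is exactly invertible.
Candidate topologies are deduplicated by a canonical rooted-topology
string (children ordered by smallest contained leaf label).

## Likelihood evaluation

Topologies are scored with Felsenstein's pruning algorithm under the
empirical amino-acid models JTT and LG (exchangeabilities and stationary
frequencies shipped as PAML-format text files; values from Jones, Taylor &
Thornton 1992 and Le & Gascuel 2008). Options:

* **+G**: discrete gamma with `n_categories` (default 4) equal-probability
  categories; category rate = mean of its inter-quantile slice (Yang 1994),
  so rates average exactly one. A median-based variant is available.
* **+I**: a proportion `p_inv` of invariant sites; variable-category rates
  are rescaled by 1/(1−p_inv), and the invariant class contributes the
  stationary probability of the residue at sites that can be constant.
* **+F**: stationary frequencies re-estimated from the alignment
  (renormalized over the 20 canonical residues).

Rate matrices are scaled to one expected substitution per site per unit
branch length. Transition matrices come from the eigendecomposition of the
π^1/2-symmetrized generator, so P(t) for any t costs one 20×20
reconstruction. Gaps and `X` are missing data (partial likelihood of one).
Site patterns are compressed, and partial likelihoods carry per-pattern log
scaling factors against underflow. Under these reversible models the
likelihood is invariant to root position (verified to 1e−8 in tests); this
invariance matters for interpretation, below.

Branch lengths are optimized by cyclic one-dimensional search: each sweep
recomputes subtree partials post-order, then walks the tree pre-order
maintaining exactly current above-edge partials while optimizing each
branch with bounded Brent (lengths in [1e−8, 20]). Because every
one-dimensional step uses fully consistent partials, each step is true
coordinate ascent and the likelihood is non-decreasing across sweeps;
convergence is declared when a sweep improves the total by less than `tol`
(default 1e−6). Each branch's profile likelihood is factored through the
spectral decomposition, so one Brent trial costs O(categories × patterns ×
20). The gamma shape can be estimated by an outer one-dimensional search;
the pipeline default estimates it once on the query-less backbone and holds
it fixed across all 45 candidates (per-topology re-estimation is available
but changes nothing detectable at these sizes and triples the cost).

Two optimization modes are exposed for the placement sweep:

* `full` — every branch of every candidate topology (the default);
* `attachment` — backbone branch lengths fitted once per arrangement on
  the query-less alignment, then only the three branches created by each
  graft re-optimized. This is the strategy of evolutionary placement
  methods (EPA/pplacer); it is ~4× faster here and agrees with `full` on
  every simulated dataset we test except for exact likelihood ties (see
  "root-region identifiability"), which the approximation breaks by noise.
  The recovery test suite uses this mode; its problem size (45 topologies ×
  1000 sites × 20 replicates per scenario) reflects that choice.

## Topology weights and confidence sets

Per-topology site log-likelihoods are converted to probabilities by either

* **likelihood weights** (default): softmax of total log-likelihoods,
  i.e. an approximate posterior over topologies under equal priors — the
  natural reading of per-gene scenario probabilities that sum to one; or
* **RELL bootstrap proportions**: sites resampled with replacement, totals
  recomputed by summation, the best topology of each replicate scoring one
  with ties split equally (default 10,000 replicates; a seed is mandatory).

A Kishino–Hasegawa-style one-standard-error set accompanies the weights:
topology t is a member when ΔlnL(t) ≤ SE(t), with SE(t) the standard
deviation over sites of the per-site difference to the best topology scaled
by √n_sites. The maximum-likelihood topology is always a member. Full
hypothesis tests (AU, SH) are out of scope.

## Event timing and scenario summaries

An event model maps every internal backbone node to a duplication event,
many-to-one: the three paralog-pair nodes map to the single cluster
duplication (the focal event); the two tandem duplications, the KCNA4
split and the KCNA7 split are one node each. Nodes sharing an event must be
pairwise non-ancestral.

For each candidate placement, the node created by the graft is read as the
cyclostome–gnathostome speciation S. An event is **before** the split if
any of its nodes is a strict ancestor of S, else **after** if any of its
nodes descends from S, else **undetermined** (all its nodes in "uncle"
subtrees that the topology cannot order against S). Duplications are
counted per node but timed per event — linking the three pair nodes into
one event is what lets a single placement push all seven backbone
duplications before the split. The focal event's timing defines the
scenario: before → II, after → I, undetermined → ambiguous. On the KCNA
backbone this rule partitions the 45 candidates into 21 scenario-I, 18
scenario-II and 6 ambiguous topologies.

Weighted summaries follow the stated convention that ambiguous placements
split their mass half-and-half (the prior is configurable):
P(II) = Σ w·[II] + ½ Σ w·[ambiguous], and N_bef = Σ w·(n_bef + ½·n_und),
N_aft symmetrically. For every weight vector P(I)+P(II) = 1 and
N_bef+N_aft equals the number of internal backbone nodes (7 here).

### Root-region identifiability

Grafting the query on the root slot, on the KCNA4-stem branch, or on the
KCNA7 terminal branch produces the *same unrooted topology* — all three
insert the query somewhere along the single unrooted edge between the
KCNA4-stem node and KCNA7. Since the likelihood of a reversible model
depends only on the unrooted topology, these three candidates tie exactly
after branch-length optimization and share their weight equally. One of the
three is ambiguous (KCNA7-terminal), so a family whose true history is a
basal (root) attachment can reach at most P(I) = 1/3 + 1/3 + ½·1/3 = 5/6 ≈
0.83, no matter how much data is available. The recovery suite shows
exactly this ceiling; by contrast a query truly orthologous to a cluster
gene occupies a unique unrooted topology and is recovered with P(II) ≈ 1.
This is a structural limit of unrooted likelihood placement, not an
implementation artifact, and it mirrors the equivocal support real basal
lamprey genes receive.

## Composition statistics

Codon statistics operate on in-frame CDS (frame 1, standard code); codons
containing N are skipped, stop codons and the non-degenerate ATG/TGG are
excluded from the 59-codon count tables, and internal stops are flagged and
excluded. GC3 is the G+C fraction at third codon positions (all codons,
including ATG/TGG and terminal stops, minus N-containing ones). Species- or
dataset-level statistics are computed on the concatenated coding sequence
(a per-gene mean is available as an alternative aggregate).

ENc uses Wright's estimator: per amino acid with n ≥ 2 observed codons,
F̂ = (n·Σp̂² − 1)/(n − 1); F̄ averaged within the degeneracy classes
{2: 9 amino acids, 3: Ile, 4: 5, 6: Leu/Ser/Arg — kept at their true
degeneracy}; ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to [20, 61].
Families with F̂ ≤ 0 (possible at tiny n) carry no signal and are dropped
from their class average. A missing 3-fold class is imputed as (F̄₂+F̄₄)/2;
any other missing class contributes its amino acids at the mean
codons-per-amino-acid of the observed classes; fewer than two observed
classes yields a missing value. Exact scale invariance of F̂ holds only
asymptotically, so the invariance test runs at n ≥ 1000 codons. The
no-selection reference curve is ENc(s) = 2 + s + 29/(s² + (1−s)²) with
s = GC3.

RSCU is the observed codon count divided by its within-family mean (family
sums equal the degeneracy; absent families give missing values).
Amino-acid composition pools sequences before counting (order-invariant;
X and gaps ignored).

## Correspondence analysis and within-group CA

CA is the standard chi-square decomposition: P = X/n, residuals
S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD, principal coordinates by mass
scaling; total inertia equals χ²/n (asserted against an independent χ²
computation in tests). All-zero rows/columns are dropped with a warning; a
rank-0 table yields zero axes. Axis signs are fixed by making the first
nonzero column loading positive, and all tests treat sign as arbitrary.

WCA removes between-amino-acid structure before ordination: each cell is
replaced by its deviation from the expectation given the row's family total
and the table-wide within-family profile, x_gc − T_ga·m_{c|a}, with row and
column masses retained from the original table. Rows that share
within-family codon proportions therefore have zero within-group inertia
regardless of amino-acid composition — the defining property, proved by
test. Because the reference R implementation's exact mass conventions after
centering are not fully documented, we claim this formulation (and its
properties) rather than numeric identity with it; CA of the RSCU matrix is
provided as a convenience and orders synthetic species identically. The
first-axis-vs-GC3 association is reported as a plain Pearson r and r²
(|r| is the stable quantity under sign flips).

## Synthetic data

`simulate_alignment` evolves sequences down a tree under the same
JTT/LG(+G+I) machinery used for inference: root states from π, one rate
category per site, branch transitions from P(t). `simulate_family` grafts a
query onto a named backbone branch and labels the truth; scenario defaults
are II → KCNA1 terminal (query orthologous to a cluster gene), I → root
slot (query basal to the family), basal-ambiguous → KCNA4 terminal.
Default study conditions, chosen once as a realistic deep-vertebrate
regime: backbone terminals 0.3 and internals 0.15 substitutions/site,
query pendant 0.5, JTT with gamma shape α = 1.0, 1000 sites (roughly two to
five times the alignment lengths of single-gene studies, so that placement
signal rather than site sampling limits recovery).

`generate_coding_set` draws amino acids i.i.d. from a fixed composition
(default: the JTT stationary frequencies) and chooses synonymous codons
with a G/C-third-position tilt solved numerically (monotone bisection in
log-weight) so the expected GC3 equals the target; the tilt acts only on
synonymous choice, never the protein. Targets outside the attainable range
(bounded below by the Met+Trp share, both of whose codons end in G) are
clamped with a warning. `preference_strength` adds weight on one preferred
codon per family: 0 leaves usage uniform given the GC tilt (genes then sit
on Wright's null curve within ~5 ENc units), large values drive ENc to 20.

What the generators do **not** emulate: among-site compositional
heterogeneity, lineage-specific amino-acid or GC drift (the
non-homogeneous regime), alignment error, gaps, isochore structure, or
selection on codon usage beyond the single-preference knob. Passing
recovery tests therefore show the estimator chain is correct and well
calibrated under its own model class, not that real lamprey data are this
well behaved.

## Degenerate inputs and numerical conventions

Ragged alignments, illegal characters, out-of-frame CDS and duplicate
identifiers are rejected at construction. Likelihood clamps pattern
probabilities at 1e−300 before logs; transition matrices are clipped at
zero. Branch-length bounds are [1e−8, 20]; Brent tolerance defaults to
1e−6 (1e−4 in the placement sweep, where topology differences dominate).
RELL requires an explicit seed; weight vectors must sum to one within
1e−9. Ordination drops singular values below 1e−6 (squared 1e−12) and
caps the axis count at min(rows, cols) − 1.
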