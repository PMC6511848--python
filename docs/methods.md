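# Methods

## Model

The package builds a joint embedding of two (or more) protein–protein
interaction networks in one reproducing kernel Hilbert space (RKHS).

For a single unweighted, undirected network with adjacency $A$ and Laplacian
$L = \mathrm{diag}(\deg) - A$, the similarity between proteins is the
regularized Laplacian kernel $K = (I + \lambda L)^{-1}$. This kernel is the
closed-form minimizer of the guilt-by-association objective

$$\hat y = \arg\min_{y'} \sum_i (y'_i - y_i)^2 + \lambda \sum_{ij} a_{ij}(y'_i - y'_j)^2,$$

i.e. diffusion of a label vector balances fidelity to the observed labels
against smoothness over edges, and it naturally discounts paths through
high-degree nodes. $K$ is symmetric positive definite with eigenvalues in
$(0, 1]$ for any $\lambda > 0$.

Cross-species alignment proceeds by (1) factorizing the source kernel
$D_1 = C_1 C_1^{\mathsf T}$, (2) treating the target kernel's landmark rows
$D_{2L}$ as inner-product constraints against the landmark rows $C_{1L}$ of
the source factor, and (3) taking the minimum-norm solution
$\hat C_2^{\mathsf T} = C_{1L}^\dagger D_{2L}$ of the underdetermined system
$C_{1L} \hat C_2^{\mathsf T} = D_{2L}$. The factorization is unique only up
to an orthogonal rotation $C_1 \mapsto C_1 Q$; the solve and the score
matrix $D_{12} = C_1 \hat C_2^{\mathsf T}$ are invariant to it (tested).

**Assumptions.** Protein functional similarity is captured by a kernel on
the interaction network; a modest set of cross-species protein pairs
(sequence homologs) can be trusted as landmarks; the networks are unweighted
simple graphs. Multi-species use treats one species as the source and solves
each additional target independently against the same $C_1$.

**Preprocessing.** Each network is restricted to the two-core of its largest
connected component, in that order, applied once. Degree-one leaves hanging
off a common parent are topologically indistinguishable and would receive
identical scores; the two-core removes them. Node order is lexicographic
everywhere, making all matrices and outputs bit-stable.

## Parameters

| parameter | default | meaning and rationale |
|---|---|---|
| `lam` (λ) | 1.0 | Diffusion strength (dimensionless). Weighs the smoothness term equally with the fit term. Small values (≲0.1) leave the kernel near the identity: per-node self-similarity dominates and mesoscale (pathway/community) structure is invisible to downstream classifiers. λ = 1 preserves the correspondence signal and the pair-classification signal; all algebraic contracts hold for any λ > 0. |
| `n_landmarks` | 400 (capped at the candidate count) | Number of homolog anchor pairs. Performance saturates once landmarks cover the network densely; the synthetic experiments use 20% of true correspondences (≈60 of 300). |
| landmark strategy | `random` | `degree` orders candidates by average within-species degree rank (rank 1 = highest degree, ties by source id). Degree selection helps mainly when very few landmarks are used. |
| eigenvalue cutoff | 1e-10 | Eigenvalues of $D_1$ below this are dropped in the factorization, defining the embedding dimension k. |
| pseudoinverse cutoff | 1e-12 (relative) | Singular values of $C_{1L}$ below 1e-12 × the largest are treated as zero; near-singular landmark sets are logged. |
| `tau` | 0.001 quantile of finite dissimilarities | The "functionally similar" threshold for the phenolog relation; stringent by design so the hit list stays small. The scan in the acceptance run uses the 0.005 quantile because the synthetic networks are three orders of magnitude smaller than real proteomes. |
| tree grid / inner folds | {100, 250, 500} / 3 | Nested cross-validation for the random forest maximizes inner held-out AUPR over this grid; a small grid keeps a full nested 4-fold run under a minute at the default problem size. |
| simplex grid step | 0.25 (tests), 0.05 (production) | Resolution of the convex-combination search over per-species weights in multi-species function prediction. |

## Synthetic data: what it emulates, what it does not

`make_network_pair` grows a duplication–divergence graph (duplicate a random
node, retain each neighbor edge with probability 0.4, anchor to the parent
with probability 0.7), then tops up to the requested density by triadic
closure — closing open triangles preserves the local clustering that real
PPI networks show (average clustering ≈ 0.6 at the defaults), where uniform
random edges would destroy it. The target network is a relabeled copy with
`rewire_fraction` of its edges replaced by random non-edges; the relabeling
is the hidden ground-truth correspondence. Defaults: n = 300 nodes, density
0.025 (mean degree ≈ 7.5), 10% rewiring.

`degree_preserving_randomize` is a configuration-model stub matching from
the exact degree sequence with self loops and parallel edges removed
afterwards, so degrees are preserved up to small cleanup losses (despite
them, ≥95% of nodes deviate by ≤2 on the test graphs).

`plant_sl_interactions` places disjoint connected pathway neighborhoods
(BFS-grown) and pairs them into *redundant couples grown from each other's
boundary*, reflecting that redundant pathways carry the same essential
function and therefore occupy the same network region. Synthetic-lethal
positives are pairs within a pathway or spanning a couple; negatives are, by
default, sampled uniformly from non-SLI pairs — the construction used for
the benchmark SLI datasets this emulates. (A `cross_pathway` negative mode
restricted to unrelated-pathway pairs is available, but note that geometry —
positives ≈ 2μ_R against negatives ≈ μ_R + μ_{R'} — is not linearly
separable even in principle, so only nonlinear classifiers can score well on
it.)

`make_toy_ontology` builds a three-level term DAG (pathway terms → process
terms per couple → root, with `part_of` edges for relation coverage),
annotates pathway genes to their pathway term in both species, and derives
one phenotype per couple from its gene content, with a configurable noise
rate.

What passing tests on this generator do **not** show: robustness to the
noise profile of real interactomes (study-bias, false-positive edges,
incomplete coverage), to unbalanced network sizes across species, to
many-to-many homology, or to annotation sparsity; real-corpus performance
must be assessed on real data.

## Numerical choices

- Kernels are computed by Cholesky solve of $I + \lambda L$ and symmetrized
  as $(M + M^{\mathsf T})/2$ to suppress round-off asymmetry; label
  smoothing solves the linear system directly rather than forming the
  inverse.
- Factorization columns are ordered by descending eigenvalue and each
  column's sign is fixed so its largest-magnitude entry is positive, making
  the embedding deterministic.
- Non-positive cross-species scores (possible after the landmark solve) map
  to an infinite dissimilarity — never "functionally close" — and are
  excluded from means and from the phenolog relation.
- Hungarian matching always assigns every node of the smaller side; the cost
  matrix is built in lexicographic order so ties resolve deterministically.
- GO consistency (GOC): matched pairs with two empty term sets are excluded
  from the mean; one empty set contributes 0. Propagated annotations are the
  default for GOC and k-functional similarity; function prediction uses the
  specific (unpropagated) annotations. Cross-species Resnik information
  content is computed on the union corpus of the two species.
- The phenolog significance follows the classical construction: map the
  target phenotype's genes through the thresholded relation, score the
  overlap in the source universe with the hypergeometric upper tail, and
  estimate q-values by re-running the scan on label-permuted maps
  (q(t) = mean null count of p ≤ t / observed count, made monotone).
  Hypergeometric p-values are discrete and therefore conservative: under the
  null the rate of p ≤ α approaches α from below (the exact attainable rate
  is computable and is what the calibration test checks).
- Landmark pairs are excluded from every downstream evaluation pair set.

## Problem sizes

The test suite and the acceptance script run the full pipeline at n = 300
nodes with 99 degree-null permutations, 100 phenolog permutations, 4-fold
(×3 inner) cross-validation with up to 500 trees, and 10 generator seeds for
the correspondence contrast — sizes chosen so a complete validation runs in
a few minutes on one CPU while every planted signal remains comfortably
detectable.

## Known limitations

- Dense linear algebra throughout: memory and time scale as O(n²)–O(n³) per
  network. Fine for model-organism cores (10³–10⁴ nodes); the human network
  is the practical ceiling.
- Only the regularized Laplacian kernel is implemented; the architecture
  accepts any PSD `KernelMatrix`, but heat/PageRank/commute-time kernels are
  not provided.
- Weighted graphs are out of scope in this version; extra edge-list columns
  are ignored with a warning.
- λ for published real-data analyses of this method is not documented
  anywhere we could verify; results at other λ should be checked with the
  λ-independence invariants in the test suite.
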