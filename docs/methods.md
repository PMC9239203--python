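# Methods

## Distance model

All UniFrac variants are sums over tree edges. For a pair of samples with
per-vertex propagated masses `u_i`, `v_i` and branch lengths `b_i`:

* **unweighted** — `Σ b_i·1[exactly one present] / Σ b_i·1[either present]`,
  on presence/absence of any descendant mass;
* **weighted, unnormalized** — `Σ b_i·|u_i − v_i|` on per-sample
  proportions;
* **weighted, normalized** — the same numerator over `Σ b_i·(u_i + v_i)`,
  confining the distance to [0, 1];
* **generalized(α)** — `Σ b_i·(u_i+v_i)^(α−1)·|u_i−v_i| / Σ b_i·(u_i+v_i)^α`
  with α ∈ [0, 1] interpolating between unweighted-like (α→0) and
  weighted-normalized (α = 1, an identity the tests verify numerically)
  behavior; vertices with `u_i+v_i = 0` contribute to neither sum;
* **variance-adjusted** — weighted by the inverse binomial standard
  deviation `1/√(m_i(m − m_i))`, where `m_i` is the pair's combined *count*
  at vertex `i` and `m` the pair's total count; vertices with
  `m_i ∈ {0, m}` contribute nothing. All quantities in this variant are
  raw counts. Published formulations vary between count- and
  proportion-based readings; the two coincide whenever the two samples have
  equal totals, which rarefaction guarantees, and the count-based form is
  what both the engine and the independent oracle implement.

The root vertex carries branch length 0 by construction (UniFrac is a sum
over edges; there is no edge above the root), so it never contributes.
A 0/0 ratio — two empty samples, or a pair with no observed tree mass —
is defined as distance 0 and reported with a warning; rarefied tables with
dropped features can legitimately produce such pairs.

## Propagation (embedding)

Trees are stored postorder (children before parents, root last), so
propagating leaf masses to the root is a single forward pass
`values[parent[i]] += values[i]`. Three modes feed the variants:
proportions (leaf counts normalized per sample), raw counts, and presence
(logical OR up the tree). Features present in the table but absent from
the tree raise an error by default, with an explicit opt-in flag to drop
them, since discarding unplaced features should be a deliberate step.

## Stripe decomposition, chunking, kernels

Stripe `k` is the vector of pairs `(i, (i+k) mod N)`; offsets `1..⌊N/2⌋`
enumerate each unordered pair once, except that for even N the last stripe
duplicates its pairs and only its first N/2 entries are kept (the
duplicate half is discarded rather than averaged — the two computations
are identical, discarding is simpler). Stripes are independent, so any
subset can be computed in isolation; the engine processes them in chunks
whose working set (≈ 3 panels of vertices × samples per stripe) fits a
configurable memory budget (default 1 GiB), or in an explicitly requested
number of chunks. Vertices are processed in blocks (default 64) for cache
locality. Results are independent of chunk count and block size up to the
floating-point summation model; tests assert bitwise equality across chunk
counts and 1e−12 agreement across block sizes.

Kernels:

* **dense** — blockwise vectorized accumulation over all (vertex, pair)
  cells;
* **sparse-aware** — consults a precomputed zero map (per-vertex nonzero
  sample indices plus per-block all-zero flags) and touches only columns
  where at least one sample of the pair has mass. The fraction of skipped
  terms is recorded and reported, not asserted: it is data-dependent
  (≈98–99% on the ~99.9%-sparse synthetic regime).
* **bit-packed** (unweighted only) — presence bits packed 64 samples per
  word; XOR/OR words expanded through a 65,536-entry 16-bit lookup table
  (the classic memory/compute trade-off) and folded against branch lengths
  as one dot product per pair, in exactly the same arithmetic form as the
  scalar kernel, so the two agree to 0 ulp in fp64.

Precision is a runtime flag, fp64 default. fp32 accumulation uses numpy's
blocked/pairwise summation, keeping error growth logarithmic; agreement
with fp64 is checked statistically (Mantel r² ≥ 0.999 on a 256-sample
instance) rather than elementwise, which is the comparison that matters
for downstream ordination.

## Container and Mantel test

Artifacts are HDF5: `/order` (ids), `/matrix` (N×N, chunked 256×256 —
full rather than condensed storage so a pair probe touches O(1) chunks),
optional `/pcoa/{eigvals,samples,proportion_explained}`, and method/alpha/
precision attributes. Symmetry, zero diagonal and finiteness are enforced
at write. The Mantel statistic is the Pearson correlation of the condensed
upper triangles after aligning the second matrix by sample id; the p-value
is one-sided (greater-or-equal) over permutations of one matrix's sample
order with the standard +1 correction, 999 permutations by default.

## PCoA

Gower double centering `B = −½·J·(D∘D)·J` followed by a dense symmetric
eigendecomposition. Eigenvalues below a noise floor of
`max|λ|·N·ε` are treated as zero; genuinely negative eigenvalues
(non-Euclidean inputs) are dropped without correction, and explained
proportions are taken over the positive spectrum only. The decomposition
is exact by design — approximate solvers would be the natural extension
for N in the hundreds of thousands, but exactness is what the closed-form
tests (two-point case, 3-D reconstruction, regular simplex) can pin down.

## Hull and sparsity analyses

Convex-hull occupancy: per environment with ≥1,000 samples, draw 1,000
samples with replacement 10 times, take the scipy `ConvexHull` volume over
the first three principal coordinates, and normalize by the hull volume of
all samples. Degenerate (coplanar) draws get volume 0 with a warning.
Sparsity scaling: per environment, draw `n` samples without replacement
(n on the powers-of-two grid 64..8192, 10 replicates) and compute the zero
fraction of the sub-table. The full feature axis is kept by default —
the denominator is what a dense table over the complete feature set would
occupy — with a flag to restrict to features observed in the subset;
the two conventions differ exactly when accumulation of samples reveals
new features, which is the effect the curve is meant to display.

## Synthetic data

`random_tree` builds a bifurcating topology by repeated random joins with
exponential branch lengths (mean 0.1, the magnitude of substitution-scaled
amplicon trees). `random_table` gives each environment a Dirichlet weight
vector (concentration 0.1, so pools overlap but differ) over all features;
each sample draws a support of `round((1 − sparsity)·n_features)` features
from its environment's pool and spreads exactly `depth` counts over it
multinomially. Defaults: depth 500 (the common rarefaction depth for
very large surveys, also this package's rarefaction default), target
sparsity 0.99, three environments. The generator reproduces marginal
sparsity, fixed sequencing depth and environment-driven beta-diversity
structure; it does not model phylogenetic signal in feature co-occurrence,
overdispersion, or the long-tailed abundance distributions of real
communities — so passing tests demonstrate algorithmic correctness and
numerical behavior, not biological realism.

Rarefaction draws a multivariate hypergeometric sample (without
replacement) per retained sample, with an RNG stream derived from
`(seed, sample position)` so results do not depend on iteration order.

The brute-force oracle recomputes every pair from scratch: per-leaf
root-ward walks build the vertex masses (a different code path from the
engine's postorder pass), and each variant formula is evaluated directly
per pair, dense, fp64, with no striping or sparsity exploitation. All
engine configurations are tested against it on randomized instances
(trees ≤ 64 leaves, tables ≤ 32 samples, sparsity 0.5–0.99 — sizes chosen
so the randomized suite exercises hundreds of instances in seconds).

## Known limitations

* Single-process only; the stripe decomposition is scheduler-ready (the
  contract requires results bitwise independent of stripe order) but no
  multiprocessing driver is included.
* No streamed/partial matrix writing: the N×N matrix exists in memory
  before the artifact is written.
* Negative-eigenvalue corrections (Lingoes/Cailliez) are not implemented.
* The variance-adjusted variant assumes count inputs; applying it to
  pre-normalized tables with unequal totals will not match
  proportion-based formulations.
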