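# Methods

## The question

Protein structural classifications (CATH: mainly-α, mainly-β, mixed α&β;
SCOP: all-α, all-β, α+β, α/β) group domains by secondary-structure content.
The study this package implements asks a geometric question: when protein
*sequences* are embedded as real vectors by alignment-free features, do the
structural classes occupy separable regions of the feature space?  Two
embeddings and two separation criteria are compared, with per-class rates
quantifying each.

## Feature extraction

**Natural vector (NV).**  For a sequence of length *n* over the 20 standard
residues, and each residue type *k*:

- `n_k` — the number of occurrences of *k*;
- `μ_k = T_k / n_k` — the mean position of those occurrences, with the
  first residue as origin (`T_k` is the sum of positions);
- `D₂ᵏ = Σᵢ (s[k][i] − μ_k)² / (n_k · n)` — the second normalized central
  moment of the positions, the j = 2 case of
  `D_j^k = Σᵢ (s[k][i] − μ_k)^j / (n_k^{j−1} n^{j−1})`.

The emitted vector is the 60-dim block layout
`⟨n_A..n_V, μ_A..μ_V, D₂^A..D₂^V⟩`.  First central moments are identically
zero and are omitted; higher moments shrink rapidly and do not change
separation results, so the vector is truncated at order 2 (the
`central_moment` function still evaluates any order).  Absent residues
contribute zeros in all three blocks.

Numerical conventions worth stating:

- *Positions are 1-based* (the first residue is position 1).  "Distance
  from the first residue" could equally mean index − 1; D₂ is invariant to
  that choice and μ only shifts by the constant 1, which both classifiers
  absorb (the MSE discriminants through the bias term, hulls through affine
  invariance).  A `origin={one_based,zero_based}` flag records the choice.
- *The denominator symbol n* in the moment normalization is the total
  sequence length, matching the natural-vector literature.
- *Residue column order* is A,R,N,D,C,Q,E,G,H,I,L,K,M,F,P,S,T,W,Y,V
  (Q before E).  Published descriptions of this feature family vary between
  Q/E orders; the order here is explicit in every column name and
  configurable at the naming layer, and no result in this package depends
  on it beyond column labeling.

**Averaged property factors (APF).**  Each residue carries the ten Kidera
factors — orthogonal physicochemical property scores (α-helix/bend
preference, side-chain size, extended-structure preference, hydrophobicity,
double-bend preference, amino-acid composition, flat-extended preference,
occurrence in α region, pK-C, surrounding hydrophobicity), standardized to
mean 0 / sd 1 over the 20 residues.  A sequence's APF vector is the
residue-average `⟨f(m)⟩_S = (1/N_S) Σ f(m)`; a sequence set's APF vector is
the unweighted mean of its per-sequence vectors (each sequence counts once,
regardless of length).  The factor table ships as
`src/structsep/data/kidera_factors.tsv`, transcribed from Kidera et al.
(1985), with a provenance header; a variant table can be substituted via
`--property-table` or `load_kidera_table(path)`.  APF is purely
compositional — every sequence permutation maps to the same vector — which
is exactly why comparing it against NV isolates the value of positional
information.

**Combined spaces.**  Feature matrices are concatenated columnwise (NV+APF
is the 70-dim augmentation).  No scaling or standardization is applied
anywhere by default; both classifiers operate on raw features, and the MSE
classifier's predictions are affine-invariant anyway.

## Classifiers

**Multi-class MSE.**  Each class *i* gets a linear discriminant
`g_i(x) = a_iᵀ(1, x)`.  With X the n × (d+1) bias-augmented sample matrix
and B the n × c one-hot indicator matrix, the weight matrix is the
least-squares solution `A = X⁺B`, minimizing `trace((XA−B)ᵀ(XA−B))`.
The pseudo-inverse is computed by SVD with relative cutoff 1e-12 rather
than `(XᵀX)⁻¹Xᵀ`: NV features are collinear by construction (counts sum to
sequence length), so the normal-equations inverse does not exist in
general.  Points classify to the argmax discriminant; exact ties break to
the earliest class in class order and are logged.

Evaluation is **resubstitution**: the classifier is fitted on all points
and those same points are re-classified, `R_i = M_i/N_i`.  This measures
separability of the given point sets, not out-of-sample generalization —
the question being asked is whether the classes occupy different regions,
not whether new proteins can be predicted.  A `cv` option is available for
users who want splits, but no reported number uses it.

One consequence documented because it surprises: under resubstitution the
expected rate for *exchangeable* labels is not 100/c.  The argmax over the
fitted one-hot regressions retains an own-label advantage of order the
leverage (d+1)/n, and the advantage decays only like √((d+1)/n) relative
to the fit noise — measured ≈ 38% (not 33.3%) for c = 3, d = 60 at
n = 6,000, and the same for i.i.d. Gaussian features.  The chance-level
control below sizes n accordingly.  A second known behavior: least-squares
on indicators can *mask* the middle class of collinear class arrangements,
so even well-separated blobs need not reach 100% when their means are
collinear; the test suite exercises the non-collinear case.

**Convex-hull exclusivity.**  Class *i*'s hull is the convex hull of its
feature points.  Membership of a point p is decided without constructing
facets (hopeless in 10-D with hundreds to thousands of generators): one LP
per query computes the minimal sup-norm distance from p to the hull —
minimize t over (λ, t) subject to |Gᵀλ − p| ≤ t, Σλ = 1, λ ≥ 0 — and p is
a member iff that distance is ≤ tol.  Thresholding a single computed
distance makes membership exactly monotone in tol, which a raw feasibility
formulation does not guarantee near the solver's own feasibility precision.
Default tol = 1e-8 (absolute, per coordinate); boundary points count as
inside.  Degenerate generator sets (fewer points than d+1) are handled
naturally — the feasible region is a lower-dimensional simplex.

`C_i = A_i/N_i` counts class-i points inside their own hull and in *no*
other class's hull.  Own-class membership holds by construction (the point
is a generator), so separation is governed by cross-class memberships;
points of other classes inside hull i affect only their own exclusivity.
High-dimensional features are evaluated block-by-block in consecutive
10-column blocks: for the NV these are N1/N2 (count halves, residues
A..I / L..V), Mu1/Mu2 (mean-position halves), and D1/D2 — interpreted as
the first and second halves of the twenty second-moment columns, since the
emitted vector contains no first-moment entries.  A full-dimension mode
exists for small d.

## Synthetic data generator

The generator emulates the statistical structure the features respond to,
at the scale of the real study designs:

- per-class residue-composition profiles, drawn from a symmetric
  Dirichlet (concentration 5 by default; larger → closer to uniform) or
  supplied explicitly — this drives the NV count block and APF;
- per-class, per-residue positional anchors in [0,1] with clustering
  weight w (default 0.3): residue instances are ordered by the key
  (1−w)·U + w·anchor[residue], so residues of a type cluster near their
  anchor — this drives the μ and D₂ blocks.  w = 0 is a uniform shuffle;
- a separation knob δ ∈ [0,1] interpolating all class profiles *and*
  anchors toward their across-class means; δ = 1 makes the classes
  identically distributed;
- lengths uniform on [100, 400] (typical domain lengths), 3 classes of
  150 sequences by default, mirroring the smaller CATH designs.

Default δ = 0.8, chosen once so the default study sits in the
partial-overlap regime real structural classes exhibit (NV MSE rates in the
low-to-mid 80s rather than a saturated 100%).  All randomness flows from a
single seed; FASTA output is byte-stable.

What the generator does **not** emulate: secondary-structure propensities,
homology, length–class correlations, or any physical chemistry.  Passing
tests on synthetic data therefore demonstrate that the pipeline measures
composition/position class structure correctly — not that real CATH/SCOP
classes are separable, which only the real feature sets can show.

## Verification design

Every feature extractor is checked elementwise against an independent
brute-force implementation (plain loops over the defining formulas) on
1,000 random sequences of length 5–500 (NV, tolerance 1e-12) and 500
sequences (APF), plus property tests: count conservation, D₁ ≡ 0, origin
invariance of D₂, reversal symmetry, permutation invariance and convexity
bounds of APF, concatenation mixing.  The MSE fit is checked against a
closed-form 2×2 solution and a dense least-squares oracle (50 random
instances, 1e-8), plus affine invariance and residual optimality.  Hull
membership is checked against explicit-facet oracles in 2-D and 3-D (200
random queries each), with affine invariance, nesting (an enclosed class
has C = 0), disjointness (C = 100), and tolerance monotonicity on
boundary-adjacent queries.

Two Monte-Carlo controls bracket the synthetic study: near-disjoint
compositions (each class ≥95% of its mass on its own residue slice) must
drive count-block MSE and hull rates to ≥95%, and identical classes
(δ = 1) must keep resubstitution MSE within ±10 points of 100/3% — the
latter run at 2,000 sequences/class so the resubstitution bias discussed
above stays inside that band.

## Problem sizes

The shipped analysis and the acceptance script run the default design
(3 × 150 sequences), ten seeds of the 3 × 30 separable control, and five
seeds of the 3 × 2,000 chance control; together they complete in about a
minute on one CPU.  Hull classification cost is one LP per
(point, other-class, block) triple and dominates at larger designs.

## Limitations

- The headline quantities here are computed on synthetic data; the
  original study's numbers for real CATH/SCOP sets depend on its published
  feature-vector supplements, which this package can ingest as external
  TSV blocks but does not bundle.
- Resubstitution rates overstate generalization by construction; they are
  the intended separability measure, not accuracy estimates.
- PseAAC and PSSM feature construction are out of scope; such matrices can
  be ingested as external blocks but are not computed.
- The hull LP decides membership to a tolerance; results within ~1e-9 of a
  hull boundary depend on that tolerance, which is why it is explicit and
  monotone.
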