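# Methods

## Graph model and reverse degrees

A molecular graph is the hydrogen-suppressed heavy-atom graph: vertices are
heavy atoms, edges are bonds, and bond orders, charges and stereochemistry
are ignored (an aromatic or double bond contributes one edge). Graphs must
be simple and connected with p ≥ 2 vertices and q ≥ 1 edges; disconnected
input is rejected rather than repaired — a degraded polymer (fragments) is
analyzed by passing each fragment separately. Vertex labels are opaque
strings and all outputs iterate in canonical sorted order, so results are
independent of input order.

The reverse degree is Υ(v) = Δ − d(v) + 1 with Δ the maximum degree **of the
input graph itself**, never a global constant. This matters: Υ values of a
subgraph change when it is embedded in a larger structure. Two exact integer
identities are enforced throughout the test suite:
min Υ = 1 (attained at maximum-degree vertices) and
∑<sub>v</sub> Υ(v) = p(Δ+1) − 2q. The familiar degree-sum shortcut
∑ d(v) = 2q does **not** carry over to reverse degrees; the vertex entropy
therefore normalizes by the true sum p(Δ+1) − 2q. A derivation that
substitutes 2q for the reverse-degree sum is incorrect, and this package
deliberately does not reproduce it.

## Indices and the edge partition

Every index is an edge sum ∑ F(Υ<sub>r</sub>, Υ<sub>s</sub>), so the
multiset of sorted reverse-degree pairs with multiplicities (the *edge
partition*) is a sufficient statistic. The partition route is the production
path; `brute_force_index` recomputes the same sum edge by edge with no
caching and serves as the independent oracle in tests (equality to 1e−9
relative on 200 seeded random graphs).

Conventions:

- ABC weight at (1,1) is 0 (the numerator a+b−2 vanishes); such classes
  contribute nothing to indices and entropies.
- The augmented-Zagreb weight is *undefined* at (1,1) (zero denominator
  cubed). This raises a domain error naming the class; batch APIs record the
  entry as undefined instead of aborting. It is an error rather than ±inf
  because a (1,1) class means two adjacent maximum-degree vertices, for
  which the index is simply not defined in this form.
- The Balaban-type weight uses the prefactor q/(q−p+2) exactly as the
  reverse-degree variant defines it, with (p, q) taken from the input graph;
  it is unavailable on parameterized partitions, which carry no vertex
  count.
- Randić α is restricted to {1, −1, ½, −½} by default; `allow_any_alpha`
  lifts the restriction for exploration. mM₂ is the alias Randić(−1) and
  inverse-sum-indeg the alias ReZG₂; aliases evaluate identically by
  construction.

## Entropies

The edge-weight entropy is the Shannon entropy of p(rs) = F(rs)/T,
T = ∑F, computed as log T − (1/T)∑ c·F·log F over classes with the
0·log 0 = 0 convention. It satisfies 0 ≤ E ≤ log q with equality at log q
iff all per-edge weights are equal. Arithmetic is in natural log with a
final division by ln(base), so base conversion is exact to machine
precision; the base (default e) is recorded in every result.

`displayed_form_entropy` replicates a class-aggregated variant in which each
class contributes log(count·F^F) once — i.e. the class count enters the
logarithm instead of multiplying it. This is **not** equivalent to the
Shannon form (for the HA-PTX family at s=1 with the M₁ weight it gives
6.3063 versus 4.5537) and is provided only as a diagnostic for comparing
against tabulations computed that way. Published numeric entropy tables for
the HA-PTX family match neither form under base e, 2 or 10; the package
therefore asserts only the qualitative behavior — every measure strictly
increasing in s — which both forms reproduce.

## Parameterized families

A `ParameterizedPartition` holds classes whose counts are slope·s +
intercept, validated so counts are nonnegative for all integer s ≥ s_min
(default 1; the s < 1 degradation regime is out of scope). Indices are
linear in class counts, so each index of the family is an exact affine form
obtained symbolically: slope = ∑ class_slope·F, intercept = ∑
class_intercept·F. Entropies are not affine in s and are tabulated
numerically. The packaged HA-PTX fixture has nine classes and q(s) = 96s;
its M₁, HM and forgotten closed forms (664s+4, 4684s+60, 2418s+30) are
integer-exact and its ABC form is 62.6009s − 0.1082 at four decimals. The
derived M₂ form is 1133s + 15 and the GA form 94.4586s + 0.0041; both are
verified against the class-wise sum rather than any printed value.

## QSPR harness

`QSPRModel.fit()` returns a `QSPRResults` with coefficients, metrics,
`summary()` and `equation()`. Choices a user should know:

- **Metrics are in-sample** on all rows (Pearson r between predictions and
  observations, R² = 1 − SSres/SStot, MSE); no train/test split is applied,
  and with 13 compounds none would be meaningful. Constant predictions get
  r = 0 with a warning.
- **Standardization.** Ridge/lasso/elastic-net/SVR standardize predictors to
  zero mean and unit variance internally (zero-variance columns dropped with
  a warning); coefficients are reported back on the original scale, and the
  two parameterizations agree in prediction to 1e−8 by test. OLS is fit
  unstandardized via least squares; rank-deficient designs (n ≤ p) return
  the minimum-norm solution with a prominent warning.
- **Penalties** follow scikit-learn's conventions: lasso/enet minimize
  (1/2n)‖y − Xβ‖² + λ(·), so full shrinkage occurs at λ_max =
  max|X_stdᵀ(y−ȳ)|/n (`lasso_lambda_max`); coordinate descent runs to
  tolerance 1e−7. Defaults: ridge λ=1, lasso λ=0.1, enet λ=0.1/mix=0.5, SVR
  RBF with C=100, ε=0.1, γ=1/p. All are explicit and overridable; a
  leave-one-out grid search is provided rather than hiding a tuned value.
- `equation()` renders `PROP = intercept + (coef) NAME + …`, omitting
  exactly-zero coefficients, so sparse lasso models print compactly.
  Nonlinear-kernel SVR has no linear equation and raises.

## Packaged data

`data/haptx_edge_partition.csv` is the nine-class HA-PTX family partition.
`data/drug_descriptors.csv` and `data/drug_properties.csv` are a
transcription of published 13-drug descriptor and property tables. The
available rendering of those tables runs numbers together without
delimiters, so the transcription was reconstructed and validated three ways:
exact re-concatenation against the source text, recomputation of descriptor
rows from the drug structures, and — for two rows — exhaustive tokenization
filtered by integer-programming feasibility over degree-pair multisets,
which left a unique candidate in each case. Two rows had lost one character
in the source rendering; the multiset-consistent value was restored. Note
the descriptor values in that published table are plain degree-based index
values (a reverse-degree AZI would be singular on every listed drug); they
are packaged as printed and treated as generic descriptors by the harness.
Property columns: BP, EoV, FP, MR, MV, P, MW, MM, PSA, HAC, C (units in the
CSV header).

## Synthetic graphs

`random_connected_graph(n, extra_edges, seed)` draws a uniform random
labeled spanning tree (networkx) and adds distinct non-tree edges chosen by
a seeded generator; it is deterministic per seed and always satisfies the
graph invariants. It emulates connectivity structure only — degree
distributions of real molecules (valence ≤ 4, ring statistics) are not
modeled — so property tests on these graphs certify algebraic correctness
of the index/entropy machinery, not chemical realism. Test batches use 200
graphs with n ≤ 30, which exercises every weight including singular and
context-dependent cases while keeping the suite under a few seconds.

## Known limitations

- No aromaticity perception, coordinates, stereochemistry or InChI; SMILES
  handling is connectivity only and rejects multi-fragment input.
- Balaban-type closed forms over families are unsupported (no affine vertex
  count is available).
- The QSPR harness accepts any descriptor table but ships only the 13-drug
  fixture; with n = 13 the full 9-descriptor OLS is ill-conditioned and its
  coefficients should not be interpreted.
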