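# revent

Reverse-degree topological indices, edge-weight graph entropies and QSPR
regression for molecular graphs.

`revent` is a small cheminformatics toolkit for three connected tasks:

1. **Reverse-degree descriptors.** For a hydrogen-suppressed molecular graph
   *Z* with maximum degree Δ, the *reverse degree* of a vertex *v* is
   Υ(v) = Δ − d(v) + 1 (always ≥ 1). A family of topological indices is then
   computed as edge sums ∑<sub>rs∈E(Z)</sub> F(Υ<sub>r</sub>, Υ<sub>s</sub>)
   for sixteen weight functions F: Randić R<sub>α</sub> (α ∈ {1, −1, ½, −½}),
   ABC, GA, the Zagreb family M₁/M₂/HM/mM₂, forgotten F, augmented Zagreb,
   a Balaban-type weight, redefined Zagrebs ReZG₁–₃, harmonic, SDD and
   inverse-sum-indeg.
2. **Edge-weight entropies.** Each weight induces a probability distribution
   p(rs) = F(rs)/∑F over edges; its Shannon entropy
   E<sub>F</sub>(Z) = −∑ p log p quantifies structural heterogeneity. Vertex
   information entropies and a class-aggregated diagnostic variant are also
   provided, with selectable logarithm base (e, 2, 10).
3. **Polymer families and QSPR.** Edge partitions whose class counts are
   affine in a repeat parameter *s* (degree of polymerization) yield exact
   closed forms *slope·s + intercept* for every index; the packaged fixture
   is the nine-class hyaluronic acid–paclitaxel (HA-PTX) conjugate family.
   A regression harness (OLS, ridge, lasso, elastic net, SVR) relates
   descriptor tables to physicochemical drug properties, with packaged
   13-drug descriptor and property tables.

## Worked example

Closed-form indices of the HA-PTX family (edge counts such as 19s−1 per
reverse-degree class, q(s) = 96s):

```sh
$ revent family --builtin haptx --weights m1,hm,forgotten,abc --closed-form
weight,slope,intercept
m1,664,4
hm,4684,60
forgotten,2418,30
abc,62.6009,-0.108183
```

Read: the first reverse Zagreb index of the conjugate with polymerization
degree *s* is exactly 664s + 4; the ABC index is 62.6009s − 0.1082. Entropy
curves over *s* (natural log):

```sh
$ revent family --builtin haptx --weights m1,abc --entropy --s 1..5
s,m1,abc
1,4.553688,4.563299
2,5.247017,5.256477
3,5.652545,5.661953
4,5.940259,5.949640
5,6.163421,6.172787
```

Every measure rises strictly with *s* toward the uniform ceiling ln(96s):
longer polymers have more edges but an essentially stable class mix, so the
distribution's support grows while its shape stabilizes.

QSPR on the packaged drug tables (in-sample metrics, no split):

```sh
$ revent qspr --builtin paper --target BP --methods ols,ridge,lasso,enet --seed 1 --equation
model,pearson_r,r_squared,mse
ols,0.874520,0.764786,6695.850853
ridge,0.810311,0.656066,9790.774566
lasso,0.822475,0.676453,9210.442363
enet,0.812532,0.659840,9683.360343
# lasso: BP = 253.1416 + (-2.4128) AZI + (59.9445) mM2 + (17.9951) I + (-0.2423) F
```

The same is available as a library, statsmodels-style:

```python
from revent import QSPRModel, load_qspr_tables

X, Y = load_qspr_tables()
results = QSPRModel.from_tables(X, Y, target="BP", method="lasso", lam=0.1).fit()
print(results.summary())
print(results.equation())
```

## Notes

- Δ is recomputed for every input graph; embedding a graph in a larger one
  changes all reverse degrees. See `docs/methods.md` for conventions,
  numerical choices and known limitations, including the provenance of the
  packaged drug tables.
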