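# mvmrmr — multi-view minimum-redundancy maximum-relevance feature selection

`mvmrmr` selects compact, non-redundant feature sets from **multi-view
data**: several feature matrices ("views", e.g. copy-number alteration,
DNA methylation and expression profiles) measured on the same samples,
with one shared binary outcome such as short- vs long-term cancer
survival. It is aimed at people building predictive models from
multi-omics cohorts, where each view has thousands of features, samples
are scarce, and naive baselines (concatenate everything, or model each
view separately) either ignore cross-view redundancy or miss cross-view
complementarity.

## The method

**Single-view MRMR.** Given features *x₁…xₙ*, labels *y*, a relevance
function *f(x, y) ≥ 0* and a redundancy function *g(xᵢ, xⱼ) ∈ [0,1]*
(here |Pearson correlation|), greedy MRMR seeds the selected set *S* with
the most relevant feature and then repeatedly adds

&nbsp;&nbsp;&nbsp;&nbsp;argmax_{j ∈ Ω\S} ( f(xⱼ, y) − (1/|S|²) · Σ_{l ∈ S} g(xⱼ, xₗ) )

until |S| = k. The squared divisor is the package default (`exponent=2`);
the classical mean-redundancy form 1/|S| is available via `exponent=1`.
Shipped relevance functions: `chi2`, `f_stat` (one-way ANOVA F),
`mutual_information` (deterministic equal-width-binned plug-in estimate)
and `cfm` — the equal-weight average of the three after min-max
normalization over the candidate pool.

**Multi-view MRMR (MRMR-mv).** For *v* views with an importance
distribution *P = (p₁…p_v)*, the selector first draws a schedule *C* of
k−1 view indices i.i.d. from *P*, then picks the single most relevant
feature across **all** views, and at each later step *t* picks from view
*C[t]* the feature maximizing relevance minus the (1/|S_all|²)-scaled
redundancy against **everything selected so far in any view**. The
cross-view penalty is what lets it keep complementary features from
different views while rejecting a view-2 duplicate of a view-1 pick.
Expected per-view selection counts track *P*; an exhausted scheduled view
triggers a redraw from *P* restricted to views with candidates left.

Around the selector the package ships: a **two-stage gated filter
framework** (per-view Stage-I filters with enable gates; a Stage-II filter
that is single-view on the concatenation or multi-view), a **synthetic
multi-view generator** with planted relevant/redundant/complementary
structure and exact ground truth, and a **repeated stratified k-fold CV
harness** that fits selection and classifier inside every fold and
compares integration strategies (per-view SV, concatenation SV_C,
per-view-union SV_S, MV, Ensemble) by AUC on shared splits.

## Worked example

```python
from mvmrmr import SyntheticSpec, generate, mrmr_mv_select, recovery_score

spec = SyntheticSpec(m=300, n_views=2, n_features=40, n_relevant=6,
                     n_cross_pairs=2, rho_cross=0.95, effect_size=1.0, seed=42)
mvd, truth = generate(spec)

for P in [(0.5, 0.5), (0.8, 0.2), (0.2, 0.8)]:
    result = mrmr_mv_select(mvd, k=12, f="f_stat", P=P, seed=7)
    counts = [len(ix) for ix in result.per_view_indices]
    precision, recall = recovery_score(result, truth)
    print(f"P={P}: per-view counts {counts}, "
          f"recovery precision {precision:.2f}, recall {recall:.2f}")
```

prints

```
P=(0.5, 0.5): per-view counts [6, 6], recovery precision 1.00, recall 1.00
P=(0.8, 0.2): per-view counts [9, 3], recovery precision 0.83, recall 0.83
P=(0.2, 0.8): per-view counts [2, 10], recovery precision 0.75, recall 0.75
```

Each view planted 6 class-associated features among 40. Under uniform *P*
the selector splits its 12 picks evenly and recovers all 12 planted
signals (precision = recall = 1). Skewing *P* toward one view forces
picks from that view's noise once its 6 signals are exhausted, so both
precision (fraction of picks carrying planted signal) and redundancy-aware
recall (distinct signals recovered, a selected copy crediting its
original) drop — the price of a misspecified view prior.

The `examples/` directory holds one short script per capability
(single-view selection, multi-view selection, the two-stage pipeline, the
strategy comparison, the P-sensitivity sweep, table I/O and
preprocessing). A thin CLI covers the same ground from a shell:

```bash
mvmrmr simulate --out sim/ --m 300 --n-features 50 --seed 1
mvmrmr select   --config run.yaml
mvmrmr evaluate --config run.yaml --strategies MV,SV_C
```

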