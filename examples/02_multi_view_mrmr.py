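"""Multi-view MRMR with a view-importance distribution P.

Generates a two-view dataset with planted relevant features and a
cross-view redundant pair, then runs MRMR-mv at three settings of P.
P shifts where selections come from; the cross-view penalty keeps the
planted copy out while its original is selected.
"""

from mvmrmr import SyntheticSpec, generate, mrmr_mv_select, recovery_score

spec = SyntheticSpec(
    m=300, n_views=2, n_features=40, n_relevant=6,
    n_cross_pairs=2, rho_cross=0.95, effect_size=1.0, seed=42,
)
mvd, truth = generate(spec)

for P in [(0.5, 0.5), (0.8, 0.2), (0.2, 0.8)]:
    result = mrmr_mv_select(mvd, k=12, f="f_stat", P=P, seed=7)
    counts = [len(ix) for ix in result.per_view_indices]
    precision, recall = recovery_score(result, truth)
    print(
        f"P={P}: per-view counts {counts}, "
        f"recovery precision {precision:.2f}, recall {recall:.2f}"
    )

print(
    "Per-view counts track P (the first pick is always the globally most "
    "relevant feature, regardless of P). Precision counts selected features "
    "that carry planted signal; recall counts distinct planted signals "
    "recovered, with a selected copy crediting its original."
)
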