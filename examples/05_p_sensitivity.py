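"""Sensitivity of the multi-view model to the view-importance prior P.

Evaluates MRMR-mv at eleven settings P = (p1, 1-p1) and summarizes each
k's spread of mean AUCs as the percent relative range,
100 * (max - min) / mean. Larger selections are less sensitive to P: with
more picks, both views' signal gets in regardless of the schedule.
"""

from mvmrmr import CVProtocol, SyntheticSpec, generate, p_sensitivity

mvd, _ = generate(
    SyntheticSpec(
        m=200, n_views=2, n_features=25, n_relevant=8,
        n_cross_pairs=12, rho_cross=0.85, effect_size=0.9, seed=1,
    )
)

frame = p_sensitivity(
    mvd,
    k_grid=[2, 8, 20],
    learner="logistic_l1",
    protocol=CVProtocol(n_folds=3, n_repeats=1, seed=1),
)
print(frame.pivot(index="p1", columns="k", values="mean_auc").round(3).to_string())
print("\npercent relative range by k:")
for k, value in frame.attrs["prr"].items():
    print(f"  k={k:2d}: {value:.1f}%")
print("The relative range shrinks as k grows — the P prior matters less.")
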