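"""Steering the two decomposition terms of a synthetic panel.

The generator draws 31-unit, 3-group panels in which the within-group
concentration α and the between-group skew control T_intra and T_inter
separately. Averaging over seeds shows the monotone response — the
property that makes the decomposition testable by construction.
"""

import numpy as np

import theildecomp as td


def mean_components(alpha, skew, seeds):
    within, between = [], []
    for seed in seeds:
        config = td.ScenarioConfig(
            years=(2013,), indicators=("beds",), base_levels={"beds": 45.0},
            inequality=alpha, between_skew=skew, seed=seed,
        )
        panel, partition = td.generate_panel(config)
        shares = td.build_share_vector(panel.year_slice(2013), "beds")
        dec = td.decompose(shares, partition)
        within.append(dec.within)
        between.append(dec.between)
    return np.mean(within), np.mean(between)


seeds = range(40)

print("Within-group concentration alpha -> mean T_intra (skew held uniform):")
for alpha in (2.0, 20.0, 200.0):
    w, _ = mean_components(alpha, 1.0, seeds)
    print(f"  alpha = {alpha:6.0f}   T_intra = {w:.4f}")
print("  -> larger alpha pins unit shares to population shares, T_intra ~ 1/(2*alpha).")

print()
print("Between-group skew spread delta -> mean T_inter (alpha held at 50):")
for delta in (0.0, 0.3, 0.6):
    skew = tuple(float(np.exp(d)) for d in (delta, 0.0, -delta))
    _, b = mean_components(50.0, skew, seeds)
    print(f"  delta = {delta:.1f}      T_inter = {b:.4f}")
print("  -> uniform skew (delta 0) forces T_inter to zero; widening the")
print("     per-capita gradient across groups raises it monotonically.")
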