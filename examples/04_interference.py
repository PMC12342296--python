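"""Quantify crossover interference two ways: gamma fit and CoC curve.

On SCs with exactly two MLH1 foci, the inter-focus distance distribution
is fitted with a gamma law whose shape γ measures interference strength
(γ = 1 none, larger = stronger).  Independently, the coefficient of
coincidence (observed/expected double-CO frequency per segment pair)
shows how interference decays with inter-interval separation.
"""

import meioco as m

ds28, _ = m.rank_dataset(m.simulate_dataset(m.condition_preset(28.0, n_cells=200, seed=8)))
ds20, _ = m.rank_dataset(m.simulate_dataset(m.condition_preset(20.0, n_cells=200, seed=9)))

for label, ds, nu in (("28 °C", ds28, 8.35), ("20 °C", ds20, 6.51)):
    d = m.inter_focus_distances(ds, cross_centromere=False)
    fit = m.fit_gamma_ml(d)
    lo, hi = fit.shape_ci
    print(f"{label}: gamma shape {fit.shape:.2f} (95% CI {lo:.2f}–{hi:.2f}, "
          f"n={fit.n} two-CO SCs; generative ν = {nu})")
print("  -> weaker interference (lower γ) under thermal stress\n")

curve = m.coc_curve(ds28, n_intervals=20)
print("CoC by separation (fraction of arm length), 28 °C:")
for s, v in zip(curve.separations[::3], curve.coc[::3]):
    print(f"  d = {s:.2f}: CoC = {v:.2f}")
dist, reached = m.interference_distance(curve)
tag = "" if reached else " (never reaches 1: interference spans the whole arm)"
print(f"interference distance (CoC = 1): {100*dist:.0f}% of arm length{tag}")
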